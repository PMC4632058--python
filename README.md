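# ldknni — LD-kNNi genotype imputation for unordered SNP markers

Genotyping-by-sequencing (GBS) and similar reduced-representation assays
deliver cheap genome-wide SNP genotypes, but with a lot of missing calls —
often 10–50% — and, for many non-model crops and diverse germplasm panels,
with no reliable marker order and no reference haplotype panel. Standard
genotype imputation tools (Beagle, fastPHASE) need ordered, dense markers
to reconstruct haplotypes; generic matrix imputers ignore genetics
entirely. This package implements **LD-kNNi**: k-nearest-neighbor
imputation that injects linkage-disequilibrium information without ever
ordering the markers, for unphased biallelic genotypes of diploid,
heterozygous, diverse populations.

## The method

Genotypes are dosage-coded: 0 (homozygous major), 1 (heterozygous),
2 (homozygous minor); missing is −1. For samples *s₁, s₂* the
missing-aware normalized taxicab distance is

    d(s₁, s₂) = (1/n) Σₚ |g(s₁, p) − g(s₂, p)|

summed over the n SNPs observed in both samples. Plain kNNi imputes a
missing genotype at SNP *p* in sample *s* from the k genome-wide nearest
samples with a known genotype at *p*, each voting for its genotype with
weight 1/d; the highest-scoring class wins.

LD-kNNi changes one thing: for target SNP *p*, the distance is computed
only over **L(p)** — the *l* SNPs with the highest squared Pearson
correlation (r²) of dosages with *p* — plus a constant *c*:

    d_L(s₁, s₂) = c + (1/n) Σ_{q ∈ L(p)} |g(s₁, q) − g(s₂, q)|

Samples that share an evolutionary history *at the target SNP* are close
in this metric even if they are dissimilar genome-wide; *c* (default 1)
keeps the 1/d vote defined when two samples are identical on L(p).
Defaults are k = 5, l = 20, c = 1 for LD-kNNi and k = 8 for kNNi, and both
can be tuned automatically by masking known genotypes and maximizing
re-imputation accuracy under a unimodality assumption.

The package also provides the Mode baseline (per-SNP modal genotype), QC
filters (missingness, MAF, Hardy–Weinberg heterozygote excess, IBS clone
pruning), a masking-based evaluation framework (genotype error, allele
error, MAF-stratified error, allele-frequency bias, neighbor-overlap
diagnostics), and a block-LD synthetic genotype generator with an analytic
LD oracle, so everything is testable without external data.

## Worked example

```sh
ldknni simulate --n-samples 300 --n-snps 400 --block-size 20 \
    --founder-pool 8 --missing-rate 0.1 --seed 11 \
    --truth truth.tsv --observed observed.tsv
ldknni impute -i observed.tsv -o imputed.tsv --method ldknni -k 5 -l 20
ldknni evaluate -i observed.tsv --method mode --method knni --method ldknni \
    --n-mask 2000 --seed 11
```

prints

```
simulated 300x400; wrote truth.tsv and observed.tsv
wrote imputed.tsv (12084 genotypes imputed, method=ldknni)
mode: genotype error 33.50%, allele error 17.75%  (n=2000)
knni: genotype error 32.25%, allele error 17.15%  (n=2000)
ldknni: genotype error 6.65%, allele error 3.38%  (n=2000)
```

The evaluation hides 2000 known genotypes, re-imputes them, and reports
the fraction of wrong genotype calls and of wrong alleles (each genotype
carries two). On this block-LD panel the per-column Mode baseline is wrong
for a third of the hidden genotypes, genome-wide kNNi barely improves on
it, and LD-kNNi — using only the 20 most-correlated SNPs per target —
cuts the error by roughly a factor of five; allele error runs at about
half the genotype error throughout. `impute --optimize` tunes k (and l)
on a 10,000-genotype tuning mask before filling the matrix; the same
library functions are available from Python (`ldknni.impute_ldknni`,
`ldknni.masked_evaluation`, ...).

Inputs can be VCF (GT field) or a tab-delimited dosage matrix with −1 for
missing; formats are picked by extension.

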