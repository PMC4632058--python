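# Methods

## Model and assumptions

LD-kNNi treats imputation of an unphased biallelic genotype as categorical
classification over {0, 1, 2} dosage codes. Its core assumption is that
the samples most informative about a missing genotype at SNP *p* are those
most similar at the SNPs statistically correlated with *p* — not the
samples most similar genome-wide. No marker order, phase, pedigree, or
reference panel is used anywhere; chromosome/position labels are carried
through I/O as opaque annotations and consumed only by an optional
diagnostic.

Three engines share one voting rule (1/d-weighted mode over the k nearest
eligible samples) and differ in the distance:

* **Mode** — no distance; per-column modal genotype.
* **kNNi** — normalized taxicab distance over all pairwise-observed SNPs.
* **LD-kNNi** — the same sum restricted to L(p), the l SNPs with highest
  r² against the target SNP, plus an additive constant c.

Distances are always computed from the original observed data; imputed
values are never fed back, so results are independent of traversal order.

LD is squared Pearson correlation of dosage vectors over
pairwise-complete samples — the standard composite (phase-free) surrogate
for unphased diploids. Missing data are handled by pairwise-complete
deletion, which is unbiased under MCAR. Pairs with fewer than
`min_overlap` (default 2) shared samples, or zero variance on the
overlap, get r² = 0 and so sort last.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| k | neighbors voting per imputation | 5 (LD-kNNi), 8 (kNNi) | more neighbors smooth the vote toward the column mode |
| l | SNPs in L(p) | 20 | small l sharpens locality; l=0 would be undefined (l ≥ 1) |
| c | additive distance constant | 1 | any c > 0 keeps 1/d finite when samples agree on all of L(p); accuracy is insensitive to its exact value |
| min_overlap | minimum pairwise-complete samples for r² | 2 | below it correlation is undefined |

QC defaults: ≤ 20% missingness per SNP and per sample (SNPs filtered
first, then samples re-assessed), MAF ≥ 0.01, heterozygote-excess exact
test at p < 0.001, clone pruning at allele-sharing similarity > 0.9.

## Deterministic conventions

The published description of the algorithm leaves ties open; this package
fixes them so that every run is exactly reproducible:

* neighbor ties at equal distance → ascending sample index;
* vote-score ties → smaller genotype code;
* r² ties in the top-l ranking → ascending SNP index;
* kNNi neighbors at distance exactly 0 → the vote restricts to the
  zero-distance members and becomes an unweighted mode (1/d is undefined
  at zero, and only LD-kNNi carries the additive constant);
* LD-kNNi pairs with zero observed overlap on L(p) → distance = c, so the
  pair stays eligible at the maximal weight 1/c;
* a target with no eligible neighbor at all → per-column mode;
* allele-frequency recoding leaves frequency-0.5 SNPs untouched.

Because the index-based tie rules reference sample order, strict
permutation equivariance of the imputed matrix holds whenever neighbor
selection is tie-free (and always at saturating k); a global 0↔2 recoding
of a SNP flips its imputed values identically, up to vote-score ties.

The engines are vectorized (one-hot matrix products for all-pairs
distances and r²; per-SNP broadcasting for LD-restricted distances), but
every intermediate sum is an exact integer in float64, so results are
bit-identical to the naive quadratic-time definition — the test suite
asserts entry-for-entry agreement with independent brute-force
reimplementations, using exact rational arithmetic for the r² ranking
oracle so mathematical ties are compared exactly.

## Hardy–Weinberg filter

GBS paralog collapse shows up as heterozygote excess, so the HWE filter
is one-sided: conditional on the observed allele counts, the exact
distribution of the heterozygote count (Wigginton-style) gives
P(N_het ≥ observed), and SNPs below the threshold are removed. SNPs with
zero minor-allele count carry no information for the test and are
retained. Clone pruning uses IBS allele sharing,
1 − Σ|gᵢ−gⱼ| / (2·n_overlap), rather than a likelihood IBD estimator: at
a 0.9 threshold the two agree for clone detection, and IBS needs no
allele-frequency reference. Clone groups are single-linkage components
(sharing > threshold), keeping the member with the fewest missing calls.

## Parameter tuning

`optimize()` hides a fixed set of known genotypes (10,000 by default,
capped at 10% of the known entries) and scores each candidate (k, l) by
exact re-imputation accuracy on that one mask; a single shared mask makes
scores comparable across candidates. Assuming the accuracy surface is
unimodal per coordinate, each 1-D search brackets the peak by doubling
from the lower bound and finishes with an integer ternary search; for
LD-kNNi the k- and l-searches alternate (≤ 10 sweeps). The documented
defaults (5, 20) are always evaluated, and the returned optimum is the
argmax over all evaluated points, so tuning can never do worse than the
defaults on the tuning mask. All candidate evaluations reuse one masked
matrix, its distance matrix, and one full LD ranking (the top-l index for
any l is a prefix of the full per-SNP ranking).

## Evaluation framework

`masked_evaluation` hides n known genotypes drawn uniformly without
replacement, rebuilds all indices on the masked matrix (no leakage from
the hidden truth), imputes, and reports genotype error, allele error
(Σ|ĝ−g|/2N; always within [genotype_error/2, genotype_error]), the 3×3
confusion table, and genotype error per 5%-wide MAF bin (MAF taken before
masking). Evaluation masks are always drawn fresh with their own seed,
never reused from tuning.

The MAF-bias experiment mirrors the frequency-estimation use case: it
masks 20% of the genotypes of the fully observed SNPs, re-imputes them
with the whole matrix available to the index, and compares per-SNP MAF of
the re-imputed data against truth (sign convention: imputed − true).
The neighbor-overlap diagnostic counts, per masked coordinate, how many
of the k neighbors kNNi and LD-kNNi share, and reports each method's mean
LD-restricted distance to its chosen neighbors.

## Synthetic data

The generator produces the data regime the method targets: per block of
`block_size` SNPs a pool of `founder_pool` haplotypes is drawn (per-site
frequency ~ Uniform(0.05, 0.5)); each sample's two lineages pick founders
per block, re-drawn across block boundaries with probability
`recomb_rate` (default 1 → independent blocks: strong within-block LD,
none between); dosage is the haplotype sum; missingness is i.i.d.
Bernoulli. Founder pools live on their own RNG stream, so the analytic
population r² of a block (`expected_block_r2`) is reproducible
independently of the sample draws. Optional exact clones can be appended,
and a `shared_pool` flag reuses one founder pool across blocks (with
`recomb_rate` < 1 this induces cross-block LD).

What the generator does **not** emulate: depth-dependent (non-MCAR) GBS
dropout, genotyping error, allele-frequency spectra with rare variants
(founder frequencies start at 0.05), population structure, and family
relatedness. The last point matters for interpretation: with fully
unrelated synthetic samples, genome-wide kNNi holds only a small edge
over Mode, smaller than on real germplasm collections where panels
contain close relatives. Passing tests therefore demonstrate the
correctness and the qualitative method ordering, not the error rates to
expect on any particular crop dataset.

## Problem sizes and protocol choices in the checks

The end-to-end checks run the default scenario at 1000 × 1000 with 50
blocks — large enough for stable error estimates (10,000-genotype masks;
binomial SE ≈ 0.5 percentage points) while keeping the whole suite quick
on a laptop. When comparing engines on a new dataset the checks follow
the method's own protocol: each k-NN engine is first tuned on a tuning
mask (its own seed), then scored on a fresh evaluation mask; the fixed
defaults k=5/l=20 and k=8 are values tuned once on a real apple panel and
are not optimal for every dataset. Oracle-equivalence checks use 20
matrices up to 30 × 60 with 10–30% missingness, where the brute-force
references stay fast. The optimizer check compares against an exhaustive
grid over k ∈ 1..15, l ∈ 1..40 on a 100 × 300 matrix with the identical
tuning mask.

## Known limitations

* Accuracy degrades when no SNPs are in useful LD with the target (the
  method then approximates a noisy local mode); monomorphic columns
  cannot be imputed at all and raise an error.
* The unimodality assumption of the tuner can stall on plateaus; the
  defaults-always-evaluated guarantee bounds the damage.
* r² on dosages underestimates haplotype-level LD when phase matters;
  this is inherent to unphased input.
* VCF support covers diploid GT fields of biallelic SNPs only; other
  ploidies are rejected, other record types skipped (or rejected under
  `skip_nonbiallelic=False`).
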