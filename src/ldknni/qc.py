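"""Dataset-preparation filters for GBS genotype matrices.

The filters mirror the standard shaping steps applied to diverse
genotyping-by-sequencing panels before imputation: per-SNP/per-sample
missingness caps, a minor-allele-frequency floor, removal of SNPs with
excess heterozygosity (a paralog-collapse signature, detected with a
one-sided Hardy–Weinberg exact test), and pruning of clonal samples by
allele-sharing similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, maf

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for the QC pipeline; all fractions in [0, 1].

    Defaults: ≤20% missing per SNP and per sample, MAF ≥ 0.01, HWE
    heterozygote-excess exclusion at p < 0.001, clone pruning at
    allele-sharing similarity > 0.9.
    """

    max_missing_per_snp: float = 0.20
    max_missing_per_sample: float = 0.20
    min_maf: float = 0.01
    hwe_alpha: float | None = 0.001
    clone_ibs_threshold: float | None = 0.9

    def __post_init__(self) -> None:
        for name in (
            "max_missing_per_snp", "max_missing_per_sample", "min_maf",
            "hwe_alpha", "clone_ibs_threshold",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def filter_missingness(gm: GenotypeMatrix, cfg: QCConfig) -> GenotypeMatrix:
    """Drop SNPs then samples exceeding the missingness caps.

    SNP columns are removed first (missing fraction > ``max_missing_per_snp``),
    then sample rows are re-assessed on the surviving SNPs. This fixed order
    matters: dropping noisy SNPs can rescue borderline samples.
    """
    miss = gm.missing_mask
    keep_snps = miss.mean(axis=0) <= cfg.max_missing_per_snp
    if not keep_snps.any():
        raise ValueError(
            "all SNPs exceed the missingness threshold "
            f"{cfg.max_missing_per_snp}; raise max_missing_per_snp"
        )
    out = gm.take_snps(np.flatnonzero(keep_snps))
    keep_samples = out.missing_mask.mean(axis=1) <= cfg.max_missing_per_sample
    if not keep_samples.any():
        raise ValueError(
            "all samples exceed the missingness threshold "
            f"{cfg.max_missing_per_sample}; raise max_missing_per_sample"
        )
    return out.take_samples(np.flatnonzero(keep_samples))


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Remove SNPs with minor allele frequency below ``min_maf``.

    MAF is min(f, 1−f) with f = Σdosage / (2·n_nonmissing); all-missing
    columns are removed as well (their MAF is undefined).
    """
    m = maf(gm)
    keep = np.nan_to_num(m, nan=-1.0) >= min_maf
    return gm.take_snps(np.flatnonzero(keep))


def hwe_exact_het_excess(n0: int, n1: int, n2: int) -> float:
    """One-sided exact Hardy–Weinberg p-value for heterozygote EXCESS.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows the exact distribution of Wigginton, Cutler & Abecasis
    (2005); the returned p-value is P(N_het ≥ observed). Undefined inputs
    (fewer than two genotype classes possible) return 1.0.
    """
    n = n0 + n1 + n2
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)  # minor allele count
    if n == 0 or n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_aa = (n_rare - hets) // 2
    n_bb = n - hets - n_aa
    # log P(h) ∝ log(2^h) − log(n_aa! h! n_bb!); normalize over the support
    logp = hets * np.log(2.0) - (
        gammaln(n_aa + 1) + gammaln(hets + 1) + gammaln(n_bb + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p[hets >= n1].sum())


def filter_hwe(gm: GenotypeMatrix, alpha: float = 0.001) -> GenotypeMatrix:
    """Remove SNPs failing the heterozygote-excess exact test at level ``alpha``.

    SNPs observed as monomorphic in alleles (minor-allele count 0 — no
    variation, so the test is undefined) are retained.
    """
    keep = np.ones(gm.n_snps, dtype=bool)
    for j in range(gm.n_snps):
        col = gm.dosage[:, j]
        obs = col[col != MISSING]
        counts = np.bincount(obs, minlength=3)
        n0, n1, n2 = map(int, counts)
        if min(2 * n0 + n1, 2 * n2 + n1) == 0:
            continue
        if hwe_exact_het_excess(n0, n1, n2) < alpha:
            keep[j] = False
    return gm.take_snps(np.flatnonzero(keep))


def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing similarity, 1 − Σ|g_i − g_j| / (2·n_overlap).

    Computed over pairwise-complete SNPs. Pairs with zero overlapping SNPs
    get similarity 0 (logged). Symmetric, values in [0, 1]; the diagonal
    is 1.
    """
    d = gm.dosage
    obs = d != MISSING
    a = [((d == g) & obs).astype(np.float64) for g in (0, 1, 2)]
    cross = a[0] @ a[1].T + a[1] @ a[2].T + 2.0 * (a[0] @ a[2].T)
    absdiff = cross + cross.T
    overlap = obs.astype(np.float64) @ obs.astype(np.float64).T
    no_overlap = overlap == 0
    if no_overlap.any():
        logger.warning(
            "ibs_matrix: %d sample pairs share no observed SNPs; "
            "similarity set to 0", int(np.triu(no_overlap, 1).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - absdiff / (2.0 * overlap)
    sim[no_overlap] = 0.0
    np.fill_diagonal(sim, 1.0)
    return sim


def prune_clones(gm: GenotypeMatrix, threshold: float = 0.9) -> GenotypeMatrix:
    """Collapse clonal sample groups, keeping the most complete member.

    Samples with pairwise allele-sharing similarity > ``threshold`` are
    grouped by single linkage (transitive closure); within each group the
    sample with the fewest missing entries survives, ties broken by input
    order.
    """
    sim = ibs_matrix(gm)
    adj = csr_matrix(np.triu(sim > threshold, 1))
    n_comp, labels = connected_components(adj, directed=False)
    n_miss = gm.missing_mask.sum(axis=1)
    keep: list[int] = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        keep.append(int(members[np.argmin(n_miss[members])]))
    keep.sort()
    if len(keep) < gm.n_samples:
        logger.info("prune_clones: removed %d clonal samples", gm.n_samples - len(keep))
    return gm.take_samples(np.array(keep))


def run_qc(gm: GenotypeMatrix, cfg: QCConfig | None = None) -> GenotypeMatrix:
    """Convenience pipeline: missingness → MAF → HWE → clones.

    HWE and clone steps are skipped when their thresholds are None.
    """
    cfg = cfg or QCConfig()
    out = filter_missingness(gm, cfg)
    out = filter_maf(out, cfg.min_maf)
    if cfg.hwe_alpha is not None:
        out = filter_hwe(out, cfg.hwe_alpha)
    if cfg.clone_ibs_threshold is not None:
        out = prune_clones(out, cfg.clone_ibs_threshold)
    return out
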