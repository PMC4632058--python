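"""Pairwise linkage disequilibrium and the per-SNP top-l neighbor index.

LD here is the squared Pearson correlation (r²) of 0/1/2 dosage vectors
over pairwise-complete samples — the standard phase-free composite
surrogate for unphased diploid data. Markers are treated as unordered:
nothing in this module looks at chromosome or position.

Degenerate pairs (overlap below ``min_overlap``, or zero dosage variance
on the overlap) are assigned r² = 0 so they sort last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Minimum pairwise-complete sample count for a defined correlation.
DEFAULT_MIN_OVERLAP = 2


def r2_matrix(gm: GenotypeMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP) -> np.ndarray:
    """All-pairs r² between SNP dosage columns, pairwise-complete.

    Returns an (n_snps × n_snps) symmetric matrix with zero diagonal.
    Uses the moment identity
    r² = (n·Σxy − Σx·Σy)² / ((n·Σx² − (Σx)²)(n·Σy² − (Σy)²)),
    with every moment accumulated only over samples where both SNPs are
    observed (computed via masked matrix products, O(n·p²) in BLAS).
    """
    obs = (gm.dosage != MISSING).astype(np.float64)
    v = np.where(gm.dosage != MISSING, gm.dosage, 0).astype(np.float64)
    n = obs.T @ obs
    sx = v.T @ obs
    sxy = v.T @ v
    sxx = (v * v).T @ obs
    cov = n * sxy - sx * sx.T
    varx = n * sxx - sx**2
    denom = varx * varx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((denom > 0) & (n >= min_overlap), cov**2 / denom, 0.0)
    np.clip(r2, 0.0, 1.0, out=r2)
    np.fill_diagonal(r2, 0.0)
    return r2


def pairwise_r2(
    gm: GenotypeMatrix, i: int, j: int, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """r² between SNP columns ``i`` and ``j`` over pairwise-complete samples."""
    if i == j:
        raise ValueError("pairwise_r2 requires two distinct SNPs")
    x, y = gm.dosage[:, i], gm.dosage[:, j]
    both = (x != MISSING) & (y != MISSING)
    n = int(both.sum())
    if n < min_overlap:
        logger.debug("pairwise_r2(%d, %d): overlap %d < %d -> 0", i, j, n, min_overlap)
        return 0.0
    xf = x[both].astype(np.float64)
    yf = y[both].astype(np.float64)
    cov = n * (xf @ yf) - xf.sum() * yf.sum()
    vx = n * (xf @ xf) - xf.sum() ** 2
    vy = n * (yf @ yf) - yf.sum() ** 2
    if vx <= 0 or vy <= 0:
        logger.debug("pairwise_r2(%d, %d): zero variance on overlap -> 0", i, j)
        return 0.0
    return float(min(1.0, cov**2 / (vx * vy)))


def neighbor_order(r2: np.ndarray) -> np.ndarray:
    """Full per-SNP neighbor ranking: (p × p−1) indices by descending r².

    Ties are broken by ascending SNP index, and a SNP never ranks itself.
    Row ``p`` of the result ordered-prefixes the top-l list for every l,
    which lets callers reuse one ranking across many l values.
    """
    p = r2.shape[0]
    # lexsort: primary key -r2, secondary ascending column index
    order = np.lexsort((np.broadcast_to(np.arange(p), (p, p)), -r2), axis=1)
    return _drop_self(order)


def _drop_self(order: np.ndarray) -> np.ndarray:
    p = order.shape[0]
    mask = order != np.arange(p)[:, None]
    return order[mask].reshape(p, p - 1)


@dataclass
class LDIndex:
    """Per-SNP ranked list of the l most-correlated other SNPs.

    ``idx[p]`` holds the neighbor SNP indices of SNP ``p`` sorted by
    non-increasing r² (ties by ascending index), ``r2[p]`` the matching r²
    values; both have ``min(l, n_snps−1)`` columns.
    """

    l: int
    idx: np.ndarray
    r2: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    @property
    def n_snps(self) -> int:
        return self.idx.shape[0]

    def neighbors(self, p: int) -> list[tuple[int, float]]:
        return [(int(i), float(r)) for i, r in zip(self.idx[p], self.r2[p])]


def build_index(
    gm: GenotypeMatrix,
    l: int,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    r2: np.ndarray | None = None,
) -> LDIndex:
    """Build the top-``l`` LD index for every SNP.

    ``r2`` may be passed in to reuse a precomputed all-pairs matrix. The
    index depends only on (matrix, l, min_overlap) and is reusable across
    all imputations at that l. When the matrix has ≤ l other SNPs the
    lists are simply shorter.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if r2 is None:
        r2 = r2_matrix(gm, min_overlap)
    order = neighbor_order(r2)
    take = min(l, max(r2.shape[0] - 1, 0))
    idx = order[:, :take]
    return LDIndex(
        l=l,
        idx=idx,
        r2=np.take_along_axis(r2, idx, axis=1),
        min_overlap=min_overlap,
    )


def write_index_tsv(index: LDIndex, gm: GenotypeMatrix, path: str) -> None:
    """Diagnostic dump: one row per (snp, rank) with neighbor ID and r²."""
    with open(path, "w") as fh:
        fh.write("snp_id\trank\tneighbor_snp_id\tr2\n")
        for p in range(index.n_snps):
            for rank, (j, r) in enumerate(index.neighbors(p), start=1):
                fh.write(f"{gm.snps[p]}\t{rank}\t{gm.snps[j]}\t{r:.6g}\n")
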