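"""Imputation engines: Mode, kNNi, and LD-kNNi.

All three engines fill every missing entry of a dosage matrix and never
touch observed entries. Distances are always computed from the original
(pre-imputation) matrix, so no imputed value ever feeds back into another
imputation and results are independent of traversal order.

kNNi
    For a missing genotype of sample s at SNP p: the normalized taxicab
    distance d(s,t) = (1/n)·Σ_q |g(s,q) − g(t,q)| is computed genome-wide
    over the n SNPs q observed in both samples. The k nearest samples with
    a known genotype at p vote with weight 1/d; the winning genotype class
    is imputed.

LD-kNNi
    Identical, except the sum runs only over L(p) — the l SNPs in
    strongest LD with p (see :mod:`ldknni.ld`) — and a constant c (> 0,
    default 1) is added so the distance, and hence the vote weight, is
    always defined even for samples identical on L(p).

Deterministic tie rules (the method description leaves them open; these
are this package's conventions, chosen for reproducibility):

* equal distances → ascending sample index;
* equal vote scores → smaller genotype code;
* kNNi neighbors at distance exactly 0 → the vote is restricted to the
  zero-distance members and becomes an unweighted mode (1/d is undefined
  at 0 and kNNi has no additive constant);
* a (sample, SNP) with no eligible neighbor at all → per-column mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .ld import LDIndex, build_index

logger = logging.getLogger(__name__)

#: Additive constant of the LD-restricted distance.
DEFAULT_C = 1.0
#: Documented defaults of the two k-NN engines.
DEFAULT_K_LDKNNI = 5
DEFAULT_L_LDKNNI = 20
DEFAULT_K_KNNI = 8

_TARGET_CHUNK = 256  # targets broadcast at once per SNP (memory cap)


@dataclass
class DistanceParams:
    """Distance configuration for LD-kNNi; the metric itself is fixed (taxicab)."""

    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("the additive constant c must be > 0")


@dataclass
class NeighborSet:
    """The neighbors used for one (sample, SNP) imputation.

    ``members`` is ordered by non-decreasing distance (ties by ascending
    sample index); every member has a known genotype at the target SNP.
    """

    target: tuple[int, int]
    members: list[tuple[int, float, int]]  # (sample_index, distance, genotype)
    k: int

    @property
    def sample_indices(self) -> list[int]:
        return [m[0] for m in self.members]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def taxicab_distance(
    gm: GenotypeMatrix,
    s1: int,
    s2: int,
    snp_subset: np.ndarray | None = None,
) -> tuple[float, int]:
    """Missing-aware normalized taxicab distance between two samples.

    Sums |dosage difference| over the SNPs (optionally restricted to
    ``snp_subset``) where both samples are observed and divides by the
    number n of SNPs actually summed. Returns ``(distance, n)``;
    when n = 0 the distance is undefined and reported as NaN — the caller
    decides how to treat the pair.
    """
    if s1 == s2:
        raise ValueError("taxicab_distance requires two distinct samples")
    a, b = gm.dosage[s1], gm.dosage[s2]
    if snp_subset is not None:
        a, b = a[snp_subset], b[snp_subset]
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    d = float(np.abs(a[both].astype(np.int32) - b[both]).sum()) / n
    return d, n


def weighted_mode(
    distances: np.ndarray | "NeighborSet", genotypes: np.ndarray | None = None
) -> int:
    """Distance-weighted modal genotype of a neighbor set.

    Each neighbor votes for its genotype with weight 1/d. Score ties break
    toward the smaller genotype code. If any neighbor is at distance
    exactly 0, only zero-distance neighbors vote, unweighted.

    Accepts either a :class:`NeighborSet` or parallel distance/genotype
    arrays. An empty set raises ``ValueError`` (callers fall back to the
    column mode).
    """
    if isinstance(distances, NeighborSet):
        ns = distances
        d = np.array([m[1] for m in ns.members], dtype=np.float64)
        g = np.array([m[2] for m in ns.members], dtype=np.int64)
    else:
        d = np.asarray(distances, dtype=np.float64)
        g = np.asarray(genotypes, dtype=np.int64)
    if d.size == 0:
        raise ValueError("weighted_mode: empty neighbor set (fallback needed)")
    if (d == 0).any():
        g = g[d == 0]
        return int(np.argmax(np.bincount(g, minlength=3)))
    scores = np.zeros(3)
    for a in (0, 1, 2):
        scores[a] = (1.0 / d[g == a]).sum()
    return int(np.argmax(scores))  # argmax returns the first (smallest) maximizer


def column_mode(col: np.ndarray, snp_name: str = "?") -> int:
    """Most frequent non-missing genotype of one SNP column (ties → smaller code)."""
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"SNP {snp_name!r} has no observed genotypes; cannot impute")
    return int(np.argmax(np.bincount(obs, minlength=3)))


# ---------------------------------------------------------------------------
# Genome-wide distance matrix (kNNi)
# ---------------------------------------------------------------------------

def distance_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs normalized taxicab distances with missing-aware counts.

    Returns ``(D, N)``: D[i, j] is the distance between samples i and j
    (NaN when they share no observed SNP, NaN on the diagonal), N[i, j]
    the count of SNPs summed. |g_i − g_j| over {0,1,2} decomposes into
    one-hot cross-products, so the whole matrix reduces to six BLAS
    matmuls — exact integer sums, hence bit-reproducible.
    """
    d = gm.dosage
    obs = d != MISSING
    a = [((d == g) & obs).astype(np.float64) for g in (0, 1, 2)]
    cross = a[0] @ a[1].T + a[1] @ a[2].T + 2.0 * (a[0] @ a[2].T)
    absdiff = cross + cross.T
    n = obs.astype(np.float64) @ obs.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n > 0, absdiff / n, np.nan)
    np.fill_diagonal(dist, np.nan)
    return dist, n.astype(np.int64)


# ---------------------------------------------------------------------------
# Vectorized per-SNP prediction
# ---------------------------------------------------------------------------

def _group_by_snp(coords: np.ndarray) -> dict[int, np.ndarray]:
    """Map snp index -> positions (rows of ``coords``) targeting that SNP."""
    order = np.argsort(coords[:, 1], kind="stable")
    groups: dict[int, np.ndarray] = {}
    snps = coords[order, 1]
    bounds = np.flatnonzero(np.diff(snps)) + 1
    for chunk in np.split(order, bounds):
        groups[int(coords[chunk[0], 1])] = chunk
    return groups


def _vote(dmat: np.ndarray, genos: np.ndarray, k: int, allow_zero: bool) -> np.ndarray:
    """Vectorized Eq.-style weighted vote for a block of targets.

    ``dmat``: (T × n) distances with np.inf marking ineligible samples
    (missing at the target SNP, the target itself, or undefined distance).
    ``genos``: genotypes of the n candidate samples at the target SNP.
    Returns predictions, or −1 where a target had no eligible neighbor.
    """
    order = np.argsort(dmat, axis=1, kind="stable")  # ties -> ascending index
    top = order[:, :k]
    dd = np.take_along_axis(dmat, top, axis=1)
    gg = genos[top]
    valid = np.isfinite(dd)
    preds = np.full(dmat.shape[0], -1, dtype=np.int8)
    none = ~valid.any(axis=1)
    if allow_zero:
        # kNNi: zero-distance neighbors override with an unweighted mode
        zrows = np.flatnonzero((valid & (dd == 0)).any(axis=1))
    else:
        zrows = np.array([], dtype=int)
    # zero-distance rows are re-voted below; keep their weights finite here
    with np.errstate(divide="ignore"):
        w = np.where(valid & (dd > 0), 1.0 / dd, 0.0)
    scores = np.stack([(w * ((gg == a) & valid)).sum(axis=1) for a in (0, 1, 2)], axis=1)
    preds[~none] = np.argmax(scores[~none], axis=1).astype(np.int8)
    for t in zrows:
        zm = valid[t] & (dd[t] == 0)
        preds[t] = np.argmax(np.bincount(gg[t][zm], minlength=3))
    preds[none] = -1
    return preds


def _predict_knni(
    gm: GenotypeMatrix,
    coords: np.ndarray,
    k: int,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """kNNi predictions at the given (sample, snp) coordinates."""
    if D is None:
        D, _ = distance_matrix(gm)
    preds = np.empty(len(coords), dtype=np.int8)
    for p, rows in _group_by_snp(coords).items():
        col = gm.dosage[:, p]
        elig = col != MISSING
        targets = coords[rows, 0]
        dmat = D[targets].copy()
        dmat[:, ~elig] = np.inf
        dmat[np.arange(len(targets)), targets] = np.inf
        dmat[np.isnan(dmat)] = np.inf
        out = _vote(dmat, col, k, allow_zero=True)
        fb = out == -1
        if fb.any():
            out[fb] = column_mode(col, gm.snps[p])
        preds[rows] = out
    return preds


def _predict_ldknni(
    gm: GenotypeMatrix,
    coords: np.ndarray,
    k: int,
    c: float,
    ld: LDIndex,
) -> np.ndarray:
    """LD-kNNi predictions at the given coordinates using a prebuilt index."""
    dosage_f = np.where(gm.dosage != MISSING, gm.dosage, 0).astype(np.float64)
    obs = (gm.dosage != MISSING)
    preds = np.empty(len(coords), dtype=np.int8)
    for p, rows in _group_by_snp(coords).items():
        cols = ld.idx[p]
        col = gm.dosage[:, p]
        elig = col != MISSING
        a_val = dosage_f[:, cols]          # n × l
        a_obs = obs[:, cols]
        targets = coords[rows, 0]
        for start in range(0, len(targets), _TARGET_CHUNK):
            tchunk = targets[start:start + _TARGET_CHUNK]
            rchunk = rows[start:start + _TARGET_CHUNK]
            diff = np.abs(a_val[tchunk][:, None, :] - a_val[None, :, :])
            both = a_obs[tchunk][:, None, :] & a_obs[None, :, :]
            cnt = both.sum(axis=2)
            ssum = np.where(both, diff, 0.0).sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                dmat = c + np.where(cnt > 0, ssum / np.maximum(cnt, 1), 0.0)
            dmat[:, ~elig] = np.inf
            dmat[np.arange(len(tchunk)), tchunk] = np.inf
            out = _vote(dmat, col, k, allow_zero=False)
            fb = out == -1
            if fb.any():
                out[fb] = column_mode(col, gm.snps[p])
            preds[rchunk] = out
    return preds


def predict_at(
    gm: GenotypeMatrix,
    coords: np.ndarray,
    method: str,
    k: int | None = None,
    l: int | None = None,
    c: float = DEFAULT_C,
    ld: LDIndex | None = None,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Predict genotypes at arbitrary (sample, snp) coordinates of ``gm``.

    The coordinates are treated as missing regardless of their current
    value (callers mask them beforehand for honest evaluation); all other
    entries of ``gm`` inform the prediction. ``ld`` / ``D`` allow reuse of
    a prebuilt LD index or distance matrix.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    if method == "mode":
        return np.array(
            [column_mode(gm.dosage[:, p], gm.snps[p]) for p in coords[:, 1]],
            dtype=np.int8,
        )
    if method == "knni":
        return _predict_knni(gm, coords, k or DEFAULT_K_KNNI, D=D)
    if method == "ldknni":
        k = k or DEFAULT_K_LDKNNI
        l = l or DEFAULT_L_LDKNNI
        if c <= 0:
            raise ValueError("c must be > 0 for LD-kNNi")
        if ld is None:
            ld = build_index(gm, l)
        elif ld.idx.shape[1] < min(l, gm.n_snps - 1):
            raise ValueError(f"supplied LDIndex has fewer than l={l} neighbors")
        if ld.idx.shape[1] > l:
            ld = LDIndex(l=l, idx=ld.idx[:, :l], r2=ld.r2[:, :l])
        return _predict_ldknni(gm, coords, k, c, ld)
    raise ValueError(f"unknown method {method!r}")


def neighbor_set(
    gm: GenotypeMatrix,
    sample: int,
    snp: int,
    method: str = "ldknni",
    k: int = DEFAULT_K_LDKNNI,
    l: int = DEFAULT_L_LDKNNI,
    c: float = DEFAULT_C,
    ld: LDIndex | None = None,
    D: np.ndarray | None = None,
) -> NeighborSet:
    """The neighbor set one imputation of (sample, snp) would use.

    Diagnostic counterpart of :func:`predict_at`; applies the same
    eligibility and tie rules and returns the chosen members with their
    distances and genotypes at the target SNP.
    """
    col = gm.dosage[:, snp]
    n = gm.n_samples
    if method == "knni":
        if D is None:
            D, _ = distance_matrix(gm)
        dvec = D[sample].copy()
    elif method == "ldknni":
        if ld is None:
            ld = build_index(gm, l)
        cols = ld.idx[snp][:l]
        dvec = np.empty(n)
        for t in range(n):
            if t == sample:
                dvec[t] = np.nan
                continue
            d, n_used = taxicab_distance(gm, sample, t, snp_subset=cols)
            dvec[t] = c + (d if n_used else 0.0)
    else:
        raise ValueError(f"neighbor_set: unsupported method {method!r}")
    dvec = np.where(np.isnan(dvec), np.inf, dvec)
    dvec[col == MISSING] = np.inf
    dvec[sample] = np.inf
    order = np.argsort(dvec, kind="stable")
    members = [
        (int(t), float(dvec[t]), int(col[t]))
        for t in order[:k]
        if np.isfinite(dvec[t])
    ]
    return NeighborSet(target=(sample, snp), members=members, k=k)


# ---------------------------------------------------------------------------
# Full-matrix engines
# ---------------------------------------------------------------------------

def _fill(gm: GenotypeMatrix, preds: np.ndarray, coords: np.ndarray) -> GenotypeMatrix:
    out = gm.copy()
    out.dosage[coords[:, 0], coords[:, 1]] = preds
    return out


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Fill every missing entry with its SNP column's modal genotype."""
    coords = np.argwhere(gm.missing_mask)
    if coords.size == 0:
        return gm.copy()
    return _fill(gm, predict_at(gm, coords, "mode"), coords)


def impute_knni(gm: GenotypeMatrix, k: int = DEFAULT_K_KNNI) -> GenotypeMatrix:
    """Genome-wide k-nearest-neighbor imputation (normalized taxicab, 1/d vote)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = np.argwhere(gm.missing_mask)
    if coords.size == 0:
        return gm.copy()
    return _fill(gm, predict_at(gm, coords, "knni", k=k), coords)


def impute_ldknni(
    gm: GenotypeMatrix,
    k: int = DEFAULT_K_LDKNNI,
    l: int = DEFAULT_L_LDKNNI,
    c: float = DEFAULT_C,
    ld: LDIndex | None = None,
) -> GenotypeMatrix:
    """LD-kNNi imputation: per-SNP distances over the top-l LD partners, plus c.

    ``ld`` may be passed in to reuse an index built once per (matrix, l).
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    coords = np.argwhere(gm.missing_mask)
    if coords.size == 0:
        return gm.copy()
    return _fill(gm, predict_at(gm, coords, "ldknni", k=k, l=l, c=c, ld=ld), coords)


def impute(gm: GenotypeMatrix, method: str, **params) -> GenotypeMatrix:
    """Dispatch to one of the three engines by name."""
    if method == "mode":
        return impute_mode(gm)
    if method == "knni":
        return impute_knni(gm, k=params.get("k") or DEFAULT_K_KNNI)
    if method == "ldknni":
        return impute_ldknni(
            gm,
            k=params.get("k") or DEFAULT_K_LDKNNI,
            l=params.get("l") or DEFAULT_L_LDKNNI,
            c=params.get("c") or DEFAULT_C,
            ld=params.get("ld"),
        )
    raise ValueError(f"unknown method {method!r}")
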