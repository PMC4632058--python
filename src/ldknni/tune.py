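"""Parameter optimization for k (and l) by masked self-accuracy.

A fixed set of known genotypes is hidden once; every candidate parameter
value is scored as the fraction of hidden genotypes it re-imputes exactly.
Using ONE mask for all evaluations makes scores directly comparable — the
surface seen by the optimizer differs between parameter values only
through the parameters themselves.

The accuracy surface is assumed unimodal in each coordinate. Each 1-D
search brackets the maximum by doubling from the lower bound until the
score drops, then runs an integer ternary search on the bracket; for
LD-kNNi the k- and l-searches alternate until neither moves (at most 10
sweeps). The documented defaults (k=5, l=20) are always evaluated too, so
the optimizer can never return parameters scoring below them on the
tuning mask, and the returned optimum is the argmax over every point
visited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import MaskSet, draw_mask
from .genotypes import GenotypeMatrix
from .impute import (
    DEFAULT_C,
    DEFAULT_K_LDKNNI,
    DEFAULT_L_LDKNNI,
    distance_matrix,
    predict_at,
)
from .ld import LDIndex, neighbor_order, r2_matrix

logger = logging.getLogger(__name__)

DEFAULT_N_MASK = 10_000
#: Never hide more than this fraction of the known genotypes while tuning.
MAX_MASK_FRACTION = 0.10


@dataclass
class TuneConfig:
    """Search configuration; bounds are inclusive integer ranges."""

    n_mask: int = DEFAULT_N_MASK
    k_bounds: tuple[int, int] = (1, 50)
    l_bounds: tuple[int, int] = (1, 200)
    seed: int = 0
    method: str = "ldknni"
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if self.n_mask < 100:
            raise ValueError("n_mask must be >= 100 for a usable accuracy estimate")
        for name in ("k_bounds", "l_bounds"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}={lo, hi} is empty or invalid")
        if self.method not in ("knni", "ldknni"):
            raise ValueError("tuning supports method 'knni' or 'ldknni'")


@dataclass
class TuneResult:
    k: int
    l: int | None
    accuracy: float
    trace: list[tuple[int, int | None, float]] = field(default_factory=list)


def make_tuning_mask(gm: GenotypeMatrix, n_mask: int, seed: int) -> MaskSet:
    """Draw the tuning mask from KNOWN genotypes, capped at 10% of them.

    The cap keeps the masked matrix realistically dense on small inputs;
    the draw is uniform without replacement and seed-reproducible.
    """
    n_known = int((gm.dosage != -1).sum())
    capped = min(n_mask, int(MAX_MASK_FRACTION * n_known))
    if capped < 1:
        raise ValueError(
            f"matrix has only {n_known} known genotypes; too few to tune on"
        )
    if capped < n_mask:
        logger.info(
            "make_tuning_mask: n_mask capped from %d to %d (10%% of %d known)",
            n_mask, capped, n_known,
        )
    return draw_mask(gm, capped, seed)


class TuningWorkspace:
    """Caches everything reusable across parameter evaluations of one mask.

    The masked matrix, its genome-wide distance matrix (kNNi), and the
    full LD neighbor ranking (from which the top-l index for ANY l is a
    column prefix) are each computed lazily, once.
    """

    def __init__(self, gm: GenotypeMatrix, mask: MaskSet, c: float = DEFAULT_C):
        self.mask = mask
        self.masked = mask.apply(gm)
        self.c = c
        self._D: np.ndarray | None = None
        self._order: np.ndarray | None = None
        self._r2: np.ndarray | None = None
        self._sorted_r2: np.ndarray | None = None

    def _ld_for(self, l: int) -> LDIndex:
        if self._order is None:
            self._r2 = r2_matrix(self.masked)
            self._order = neighbor_order(self._r2)
            self._sorted_r2 = np.take_along_axis(self._r2, self._order, axis=1)
        take = min(l, self._order.shape[1])
        return LDIndex(l=l, idx=self._order[:, :take], r2=self._sorted_r2[:, :take])

    def accuracy(self, method: str, k: int, l: int | None = None) -> float:
        if method == "knni":
            if self._D is None:
                self._D, _ = distance_matrix(self.masked)
            preds = predict_at(self.masked, self.mask.coords, "knni", k=k, D=self._D)
        elif method == "ldknni":
            preds = predict_at(
                self.masked, self.mask.coords, "ldknni",
                k=k, l=l, c=self.c, ld=self._ld_for(l),
            )
        else:
            raise ValueError(f"unsupported tuning method {method!r}")
        return float(np.mean(preds == self.mask.truth))


def accuracy_at(
    gm: GenotypeMatrix,
    mask: MaskSet,
    method: str,
    k: int | None = None,
    l: int | None = None,
    c: float = DEFAULT_C,
    workspace: TuningWorkspace | None = None,
) -> float:
    """Exact-match imputation accuracy on one mask at fixed parameters.

    Masks all coordinates simultaneously, rebuilds any index on the
    masked matrix, and scores exact genotype agreement. For 'mode' the
    parameters are ignored. Pass a :class:`TuningWorkspace` to amortize
    the index/distance computations over many calls with the same mask.
    """
    if method == "mode":
        masked = mask.apply(gm)
        preds = predict_at(masked, mask.coords, "mode")
        return float(np.mean(preds == mask.truth))
    ws = workspace or TuningWorkspace(gm, mask, c=c)
    return ws.accuracy(
        method,
        k=k or (DEFAULT_K_LDKNNI if method == "ldknni" else 8),
        l=l or DEFAULT_L_LDKNNI,
    )


def ternary_search_int(f, lo: int, hi: int) -> tuple[int, dict[int, float]]:
    """Exact argmax of a unimodal integer function on [lo, hi].

    Standard integer ternary search; on plateaus it returns a maximizer
    (the smallest evaluated one). Returns (argmax, {x: f(x) evaluated}).
    """
    evals: dict[int, float] = {}

    def F(x: int) -> float:
        if x not in evals:
            evals[x] = f(x)
        return evals[x]

    a, b = lo, hi
    while b - a > 2:
        m1 = a + (b - a) // 3
        m2 = b - (b - a) // 3
        if m1 == m2:
            m2 += 1
        if F(m1) < F(m2):
            a = m1 + 1
        else:
            b = m2
    for x in range(a, b + 1):
        F(x)
    best = max(evals, key=lambda x: (evals[x], -x))
    return best, evals


def _bracketed_search(f, lo: int, hi: int) -> tuple[int, dict[int, float]]:
    """Geometric bracketing by doubling from ``lo``, then integer ternary search."""
    xs: list[int] = []
    x = lo
    while x < hi:
        xs.append(x)
        x = max(x * 2, x + 1)
    xs.append(hi)
    evals: dict[int, float] = {}

    def F(y: int) -> float:
        if y not in evals:
            evals[y] = f(y)
        return evals[y]

    a, b = lo, hi
    for i, y in enumerate(xs):
        F(y)
        if i >= 1 and evals[y] < evals[xs[i - 1]]:
            a = xs[i - 2] if i >= 2 else lo
            b = y
            break
    else:
        a = xs[-2] if len(xs) > 1 else lo
        b = hi
    best, tev = ternary_search_int(lambda y: F(y), a, b)
    evals.update(tev)
    best = max(evals, key=lambda y: (evals[y], -y))
    return best, evals


def optimize(gm: GenotypeMatrix, cfg: TuneConfig | None = None) -> TuneResult:
    """Search for the (k, l) maximizing tuning-mask accuracy.

    kNNi: a single bracketed 1-D search over k. LD-kNNi: alternating 1-D
    searches over k and l, seeded at the documented defaults (clipped to
    the bounds), until neither coordinate moves or 10 sweeps elapse. The
    result is the best point ever evaluated (ties: higher accuracy first,
    then smaller k, then smaller l) together with the full trace.
    """
    cfg = cfg or TuneConfig()
    mask = make_tuning_mask(gm, cfg.n_mask, cfg.seed)
    ws = TuningWorkspace(gm, mask, c=cfg.c)
    trace: list[tuple[int, int | None, float]] = []
    cache: dict[tuple[int, int | None], float] = {}

    def score(k: int, l: int | None) -> float:
        key = (k, l)
        if key not in cache:
            cache[key] = ws.accuracy(cfg.method, k=k, l=l)
            trace.append((k, l, cache[key]))
        return cache[key]

    klo, khi = cfg.k_bounds
    if cfg.method == "knni":
        score(min(max(8, klo), khi), None)  # documented kNNi default
        best_k, _ = _bracketed_search(lambda k: score(k, None), klo, khi)
    else:
        llo, lhi = cfg.l_bounds
        k = min(max(DEFAULT_K_LDKNNI, klo), khi)
        l = min(max(DEFAULT_L_LDKNNI, llo), lhi)
        score(k, l)
        for _ in range(10):
            new_k, _ = _bracketed_search(lambda kk: score(kk, l), klo, khi)
            new_l, _ = _bracketed_search(lambda ll: score(new_k, ll), llo, lhi)
            if (new_k, new_l) == (k, l):
                break
            k, l = new_k, new_l
    best = max(cache, key=lambda kl: (cache[kl], -kl[0], -(kl[1] or 0)))
    return TuneResult(
        k=best[0], l=best[1], accuracy=cache[best], trace=trace
    )
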