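"""Naive quadratic-time reference implementations used as test oracles.

Everything here is written with plain Python loops straight from the
method definitions (normalized taxicab distance, 1/d-weighted modal vote,
top-l LD lists by pairwise Pearson r²) and deliberately shares no code
with the package's vectorized engines. Per-class vote scores are summed
in neighbor order so that exact float comparison with the engines is
well-defined.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

MISSING = -1


def ref_taxicab(dos: np.ndarray, s1: int, s2: int, subset=None):
    cols = range(dos.shape[1]) if subset is None else subset
    total, n = 0, 0
    for p in cols:
        a, b = int(dos[s1, p]), int(dos[s2, p])
        if a != MISSING and b != MISSING:
            total += abs(a - b)
            n += 1
    return (total / n if n else float("nan")), n


def ref_r2(dos: np.ndarray, i: int, j: int, min_overlap: int = 2) -> Fraction:
    """Exact rational Pearson r² over pairwise-complete samples.

    Exact arithmetic makes the top-l ranking oracle immune to float
    jitter: mathematically tied pairs stay exactly tied.
    """
    xs, ys = [], []
    for s in range(dos.shape[0]):
        if dos[s, i] != MISSING and dos[s, j] != MISSING:
            xs.append(int(dos[s, i]))
            ys.append(int(dos[s, j]))
    n = len(xs)
    if n < min_overlap:
        return Fraction(0)
    sx, sy = sum(xs), sum(ys)
    sxy = sum(a * b for a, b in zip(xs, ys))
    sxx = sum(a * a for a in xs)
    syy = sum(b * b for b in ys)
    vx, vy = n * sxx - sx * sx, n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        return Fraction(0)
    cov = n * sxy - sx * sy
    return min(Fraction(1), Fraction(cov * cov, vx * vy))


def ref_topl(dos: np.ndarray, p: int, l: int) -> list[int]:
    others = [j for j in range(dos.shape[1]) if j != p]
    scored = sorted(others, key=lambda j: (-ref_r2(dos, p, j), j))
    return scored[:l]


def ref_column_mode(dos: np.ndarray, p: int) -> int:
    counts = [0, 0, 0]
    for s in range(dos.shape[0]):
        if dos[s, p] != MISSING:
            counts[int(dos[s, p])] += 1
    if sum(counts) == 0:
        raise ValueError("fully missing column")
    return int(np.argmax(counts))


def ref_vote(members: list[tuple[float, int]]) -> int:
    """members: (distance, genotype) in neighbor order. Ties -> smaller code."""
    if not members:
        raise ValueError("empty neighbor set")
    if any(d == 0 for d, _ in members):
        counts = [0, 0, 0]
        for d, g in members:
            if d == 0:
                counts[g] += 1
        return int(np.argmax(counts))
    scores = []
    for a in (0, 1, 2):
        s = 0.0
        for d, g in members:
            s += (1.0 / d) * (1.0 if g == a else 0.0)
        scores.append(s)
    return int(np.argmax(scores))


def _ref_neighbors(dvec: list[float], col: np.ndarray, k: int):
    """Eligible = finite distance and known genotype; sort by (d, index)."""
    elig = [
        (d, t) for t, d in enumerate(dvec)
        if d == d and d != float("inf") and col[t] != MISSING
    ]
    elig.sort(key=lambda e: (e[0], e[1]))
    return [(d, int(col[t])) for d, t in elig[:k]]


def ref_impute(dos: np.ndarray, method: str, k: int = 5, l: int = 20, c: float = 1.0):
    """Entry-for-entry reference for all three engines (original-matrix distances)."""
    out = dos.copy()
    n, p = dos.shape
    topl = {j: ref_topl(dos, j, l) for j in range(p)} if method == "ldknni" else None
    for s in range(n):
        for j in range(p):
            if dos[s, j] != MISSING:
                continue
            if method == "mode":
                out[s, j] = ref_column_mode(dos, j)
                continue
            dvec = []
            for t in range(n):
                if t == s:
                    dvec.append(float("inf"))
                elif method == "knni":
                    d, used = ref_taxicab(dos, s, t)
                    dvec.append(d if used else float("inf"))
                else:
                    d, used = ref_taxicab(dos, s, t, subset=topl[j])
                    dvec.append(c + (d if used else 0.0))
            members = _ref_neighbors(dvec, dos[:, j], k)
            out[s, j] = ref_vote(members) if members else ref_column_mode(dos, j)
    return out
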