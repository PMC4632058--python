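"""Masking-based evaluation of imputation accuracy.

The evaluation protocol hides a random set of KNOWN genotypes, re-imputes
them, and compares with the hidden truth. Two error rates are reported:

* genotype error — proportion of imputed genotypes differing from truth;
* allele error — proportion of imputed alleles differing, Σ|ĝ − g| / (2N)
  (a wrong heterozygote call costs one allele, a wrong homozygote-to-
  opposite-homozygote call costs two).

By construction genotype_error/2 ≤ allele_error ≤ genotype_error.

Any LD index is rebuilt AFTER masking, so no information from the hidden
truth leaks into neighbor selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, maf
from .impute import (
    DEFAULT_C,
    DEFAULT_L_LDKNNI,
    distance_matrix,
    impute as _run_impute,
    neighbor_set,
    predict_at,
    taxicab_distance,
)
from .ld import build_index

logger = logging.getLogger(__name__)

#: 5%-wide MAF bins: [0, 0.05), [0.05, 0.10), ..., [0.45, 0.50].
MAF_BIN_EDGES = np.arange(0.0, 0.50001, 0.05)


@dataclass
class MaskSet:
    """Coordinates hidden for evaluation, with their true genotypes."""

    coords: np.ndarray  # (m, 2) int array of (sample_index, snp_index)
    truth: np.ndarray   # (m,) genotypes in {0, 1, 2}

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.truth = np.asarray(self.truth, dtype=np.int8)
        if len(self.truth) != len(self.coords):
            raise ValueError("coords and truth lengths differ")
        if (self.truth == MISSING).any():
            raise ValueError("mask truth contains missing genotypes")
        uniq = {(int(s), int(p)) for s, p in self.coords}
        if len(uniq) != len(self.coords):
            raise ValueError("mask coordinates are not distinct")

    def __len__(self) -> int:
        return len(self.coords)

    def apply(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        """Return a copy of ``gm`` with the masked coordinates set to missing."""
        out = gm.copy()
        out.dosage[self.coords[:, 0], self.coords[:, 1]] = MISSING
        return out


def draw_mask(gm: GenotypeMatrix, n_mask: int, seed: int) -> MaskSet:
    """Sample ``n_mask`` distinct KNOWN (sample, snp) coordinates uniformly.

    Sampling is without replacement and reproducible for a fixed seed.
    """
    known = np.argwhere(gm.dosage != MISSING)
    if len(known) < n_mask:
        raise ValueError(
            f"cannot mask {n_mask} genotypes: only {len(known)} known entries"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(known), size=n_mask, replace=False)
    coords = known[pick]
    return MaskSet(coords=coords, truth=gm.dosage[coords[:, 0], coords[:, 1]])


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def genotype_error(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Proportion of genotype calls differing from truth."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted lengths differ")
    return float(np.mean(truth != predicted))


def allele_error(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Proportion of alleles called incorrectly: Σ|truth − predicted| / (2N)."""
    truth = np.asarray(truth, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted lengths differ")
    return float(np.abs(truth - predicted).sum() / (2.0 * truth.size))


def confusion_table(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """3×3 true-vs-imputed genotype counts (rows: truth, cols: imputed)."""
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (np.asarray(truth, int), np.asarray(predicted, int)), 1)
    return table


# ---------------------------------------------------------------------------
# Masked evaluation
# ---------------------------------------------------------------------------

@dataclass
class ImputationReport:
    """Everything a masked evaluation produces."""

    method: str
    params: dict
    n_mask: int
    seed: int
    genotype_error: float
    allele_error: float
    confusion: np.ndarray
    per_maf_bin: pd.DataFrame
    predictions: np.ndarray
    mask: MaskSet
    imputed: GenotypeMatrix

    def to_json(self) -> str:
        """Deterministic JSON summary (excludes the full matrices)."""
        payload = {
            "method": self.method,
            "params": {k: v for k, v in sorted(self.params.items())},
            "n_mask": self.n_mask,
            "seed": self.seed,
            "genotype_error": self.genotype_error,
            "allele_error": self.allele_error,
            "confusion": self.confusion.tolist(),
            "per_maf_bin": self.per_maf_bin.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def per_maf_bin_error(
    gm_unmasked: GenotypeMatrix, mask: MaskSet, predictions: np.ndarray
) -> pd.DataFrame:
    """Genotype error stratified by the target SNP's pre-masking MAF (5% bins)."""
    snp_maf = maf(gm_unmasked)
    bin_of_snp = np.clip(
        np.digitize(snp_maf, MAF_BIN_EDGES[1:-1], right=False), 0, 9
    )
    rows = []
    wrong = mask.truth != predictions
    mask_bins = bin_of_snp[mask.coords[:, 1]]
    for b in range(10):
        in_bin = mask_bins == b
        n = int(in_bin.sum())
        rows.append(
            {
                "bin_low": round(MAF_BIN_EDGES[b], 2),
                "bin_high": round(MAF_BIN_EDGES[b + 1], 2),
                "n_snps": int(np.sum(bin_of_snp[np.unique(mask.coords[:, 1])] == b)),
                "n_masked": n,
                "genotype_error": float(wrong[in_bin].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def masked_evaluation(
    gm: GenotypeMatrix,
    method: str = "ldknni",
    params: dict | None = None,
    n_mask: int = 10_000,
    seed: int = 0,
) -> ImputationReport:
    """Hide ``n_mask`` known genotypes, impute the masked matrix, score.

    The LD index (and the kNNi distance matrix) is rebuilt on the masked
    matrix. The report contains both error rates, the 3×3 confusion table,
    a per-MAF-bin breakdown (MAF taken from the unmasked matrix), the
    per-coordinate predictions, and the fully imputed matrix.
    """
    params = dict(params or {})
    mask = draw_mask(gm, n_mask, seed)
    masked = mask.apply(gm)
    imputed = _run_impute(masked, method, **params)
    preds = imputed.dosage[mask.coords[:, 0], mask.coords[:, 1]]
    return ImputationReport(
        method=method,
        params=params,
        n_mask=n_mask,
        seed=seed,
        genotype_error=genotype_error(mask.truth, preds),
        allele_error=allele_error(mask.truth, preds),
        confusion=confusion_table(mask.truth, preds),
        per_maf_bin=per_maf_bin_error(gm, mask, preds),
        predictions=preds,
        mask=mask,
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# Allele-frequency bias experiment
# ---------------------------------------------------------------------------

def maf_bias_experiment(
    gm: GenotypeMatrix,
    methods: dict[str, dict] | list[str],
    mask_fraction: float = 0.20,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """How strongly each imputation method biases allele-frequency estimates.

    The SNPs with zero missing data are identified; ``mask_fraction`` of
    their genotypes are hidden uniformly at random; each method re-imputes
    them using the FULL matrix (complete and incomplete SNPs alike inform
    the LD index and distances). Per complete SNP the table reports the
    true MAF (from the original matrix) and the imputed MAF (masked
    entries replaced by imputations, everything else unchanged), plus the
    signed deviation imputed − true.
    """
    complete = np.flatnonzero(~gm.missing_mask.any(axis=0))
    if complete.size == 0:
        raise ValueError(
            "no SNPs with zero missing data; supply a matrix containing a "
            "complete SNP subset (e.g. pre-filter with qc tools)"
        )
    rng = np.random.default_rng(seed)
    cells = np.stack(
        np.meshgrid(np.arange(gm.n_samples), complete, indexing="ij"), axis=-1
    ).reshape(-1, 2)
    n_hide = int(round(mask_fraction * len(cells)))
    pick = rng.choice(len(cells), size=n_hide, replace=False)
    mask = MaskSet(
        coords=cells[pick],
        truth=gm.dosage[cells[pick][:, 0], cells[pick][:, 1]],
    )
    masked = mask.apply(gm)
    true_maf_all = maf(gm)
    if isinstance(methods, list):
        methods = {m: {} for m in methods}
    out: dict[str, pd.DataFrame] = {}
    # positions of masked cells per complete SNP, resolved once
    col_of = {int(p): i for i, p in enumerate(complete)}
    for method, params in methods.items():
        if callable(params):
            # custom predictor (masked_matrix, coords) -> genotypes; lets
            # tests inject e.g. a truth oracle to calibrate the experiment
            preds = np.asarray(params(masked, mask.coords), dtype=np.int8)
        else:
            preds = predict_at(masked, mask.coords, method, **params)
        filled = gm.dosage[:, complete].copy()
        for (s, p), g in zip(mask.coords, preds):
            filled[s, col_of[int(p)]] = g
        sub = GenotypeMatrix(
            dosage=filled,
            samples=list(gm.samples),
            snps=[gm.snps[int(p)] for p in complete],
        )
        imputed_maf = maf(sub)
        out[method] = pd.DataFrame(
            {
                "snp": [gm.snps[int(p)] for p in complete],
                "true_maf": true_maf_all[complete],
                "imputed_maf": imputed_maf,
                "deviation": imputed_maf - true_maf_all[complete],
            }
        )
    return out


# ---------------------------------------------------------------------------
# Neighbor diagnostics
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Shared-neighbor diagnostic between kNNi and LD-kNNi at equal k."""

    histogram: np.ndarray        # counts of overlap size 0..k
    mean_dl_knni: float          # mean LD-restricted distance of kNNi neighbors
    mean_dl_ldknni: float        # same for LD-kNNi's own neighbors
    k: int

    @property
    def zero_share(self) -> float:
        return float(self.histogram[0] / self.histogram.sum())


def neighbor_overlap(
    gm: GenotypeMatrix,
    mask: MaskSet,
    k: int = 5,
    l: int = DEFAULT_L_LDKNNI,
    c: float = DEFAULT_C,
) -> OverlapResult:
    """Count, per masked coordinate, the neighbors shared by kNNi and LD-kNNi.

    Both methods run with the same ``k`` on the masked matrix. Also
    reports the mean LD-restricted distance (d_l) from each target to the
    neighbors each method actually uses — a measure of how much closer,
    in the relevant SNPs, LD-chosen neighbors are.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    masked = mask.apply(gm)
    D, _ = distance_matrix(masked)
    ld = build_index(masked, l)
    hist = np.zeros(k + 1, dtype=np.int64)
    dl_knni: list[float] = []
    dl_ldknni: list[float] = []
    for s, p in mask.coords:
        ns_k = neighbor_set(masked, int(s), int(p), "knni", k=k, D=D)
        ns_l = neighbor_set(masked, int(s), int(p), "ldknni", k=k, l=l, c=c, ld=ld)
        shared = len(set(ns_k.sample_indices) & set(ns_l.sample_indices))
        hist[shared] += 1
        cols = ld.idx[int(p)][:l]
        for t in ns_k.sample_indices:
            d, n_used = taxicab_distance(masked, int(s), t, snp_subset=cols)
            dl_knni.append(c + (d if n_used else 0.0))
        dl_ldknni.extend(m[1] for m in ns_l.members)
    return OverlapResult(
        histogram=hist,
        mean_dl_knni=float(np.mean(dl_knni)) if dl_knni else float("nan"),
        mean_dl_ldknni=float(np.mean(dl_ldknni)) if dl_ldknni else float("nan"),
        k=k,
    )


def same_chromosome_probability(gm: GenotypeMatrix, ld_index) -> np.ndarray:
    """Fraction of SNPs whose rank-r LD neighbor lies on the same chromosome.

    Requires chromosome labels; returns one fraction per rank 1..l. A
    diagnostic only — the imputation algorithms never see chromosome
    labels.
    """
    if gm.chrom is None:
        raise ValueError("same_chromosome_probability requires chromosome labels")
    chrom = np.asarray(gm.chrom)
    n_ranks = ld_index.idx.shape[1]
    fractions = np.empty(n_ranks)
    for r in range(n_ranks):
        fractions[r] = float(np.mean(chrom[ld_index.idx[:, r]] == chrom))
    return fractions
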