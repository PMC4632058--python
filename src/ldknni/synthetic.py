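"""Synthetic unphased diploid genotype matrices with block-LD structure.

The generator emulates the data regime the imputation method targets — a
diverse, heterozygous panel genotyped at unordered biallelic SNPs with
missing-completely-at-random dropout — using a founder-haplotype block
model:

* SNPs are grouped into blocks of ``block_size`` consecutive markers;
* each block carries a pool of ``founder_pool`` haplotypes, with per-site
  allele frequencies drawn from Uniform(maf_low, maf_high);
* each sample inherits two haplotype lineages; within a lineage the
  founder choice is re-drawn at each block boundary with probability
  ``recomb_rate`` (1.0 → independent blocks, i.e. strong LD inside a
  block and none between blocks);
* dosage = sum of the two haplotypes; blocks are grouped contiguously
  into chromosomes (labels only — nothing downstream orders markers);
* optional clones are exact row duplicates appended to the panel;
* missingness is i.i.d. Bernoulli(``missing_rate``).

Because founders are an explicit finite pool, the population LD inside a
block has a closed form (:func:`expected_block_r2`) that tests can use as
an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Generator parameters; rates are probabilities in [0, 1]."""

    n_samples: int = 1000
    n_snps: int = 1000
    n_chromosomes: int = 5
    block_size: int = 20
    founder_pool: int = 8
    maf_low: float = 0.05
    maf_high: float = 0.5
    recomb_rate: float = 1.0
    missing_rate: float = 0.10
    n_clones: int = 0
    shared_pool: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_low", "maf_high", "recomb_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.founder_pool < 2:
            raise ValueError("founder_pool must be >= 2")
        if self.block_size < 1 or self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples, n_snps and block_size must be >= 1")

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_snps / self.block_size)


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, ...]:
    """Independent streams (founders, lineages, clones, missingness).

    Separate streams keep the founder pools — and hence the analytic LD
    oracle — identical no matter how the sample-level draws are consumed.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _founder_pools(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-block founder haplotype pools (h × block_size binary arrays)."""
    sizes = [
        min(cfg.block_size, cfg.n_snps - b * cfg.block_size)
        for b in range(cfg.n_blocks)
    ]
    if cfg.shared_pool:
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.block_size)
        base = (rng.random((cfg.founder_pool, cfg.block_size)) < freqs).astype(np.int8)
        return [base[:, :s] for s in sizes]
    pools = []
    for s in sizes:
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=s)
        pools.append((rng.random((cfg.founder_pool, s)) < freqs).astype(np.int8))
    return pools


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Generate (truth, observed): a complete matrix and its MCAR-thinned copy.

    Fully deterministic for a fixed config (including seed).
    """
    rng_pool, rng_sample, rng_clone, rng_miss = _rngs(cfg)
    pools = _founder_pools(cfg, rng_pool)
    n, h = cfg.n_samples, cfg.founder_pool
    # two founder-index lineages per sample, persisted across block
    # boundaries with probability 1 − recomb_rate
    idx = np.empty((2, n, cfg.n_blocks), dtype=np.int64)
    for lineage in range(2):
        idx[lineage, :, 0] = rng_sample.integers(h, size=n)
        for b in range(1, cfg.n_blocks):
            fresh = rng_sample.integers(h, size=n)
            reshuffle = rng_sample.random(n) < cfg.recomb_rate
            idx[lineage, :, b] = np.where(reshuffle, fresh, idx[lineage, :, b - 1])
    dosage = np.concatenate(
        [pools[b][idx[0, :, b]] + pools[b][idx[1, :, b]] for b in range(cfg.n_blocks)],
        axis=1,
    ).astype(np.int8)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    if cfg.n_clones:
        src = rng_clone.choice(n, size=cfg.n_clones, replace=False)
        dosage = np.vstack([dosage, dosage[src]])
        samples += [f"{samples[s]}_clone" for s in src]
    # contiguous block groups -> chromosome labels and within-chrom positions
    chrom_of_block = np.repeat(
        np.arange(cfg.n_chromosomes),
        [len(a) for a in np.array_split(np.arange(cfg.n_blocks), cfg.n_chromosomes)],
    )
    chrom = np.repeat(
        [f"chr{c + 1}" for c in chrom_of_block],
        [pools[b].shape[1] for b in range(cfg.n_blocks)],
    )[: cfg.n_snps].astype(object)
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = np.arange(1, sel.sum() + 1)
    snps = [f"snp{j + 1:05d}" for j in range(cfg.n_snps)]
    truth = GenotypeMatrix(
        dosage=dosage, samples=samples, snps=snps, chrom=chrom, pos=pos
    )
    observed = truth.copy()
    drop = rng_miss.random(observed.dosage.shape) < cfg.missing_rate
    observed.dosage[drop] = MISSING
    return truth, observed


def founder_r2(pool: np.ndarray) -> np.ndarray:
    """Analytic population r² between the sites of one founder pool.

    A haplotype is a uniform draw from the pool, and a dosage is the sum
    of two independent draws, so dosage covariance and variance are both
    twice their single-haplotype values — r² of dosages equals r² of the
    pool columns. Zero-variance (monomorphic-in-pool) sites get r² = 0
    against everything.
    """
    hpool = pool.astype(np.float64)
    h, m = hpool.shape
    p = hpool.mean(axis=0)
    cov = hpool.T @ hpool / h - np.outer(p, p)
    var = np.diag(cov).copy()
    denom = np.outer(var, var)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, cov**2 / denom, 0.0)
    np.fill_diagonal(r2, np.where(var > 0, 1.0, 0.0))
    return np.clip(r2, 0.0, 1.0)


def expected_block_r2(cfg: SimConfig, block: int = 0) -> np.ndarray:
    """Analytic r² matrix of one block of :func:`simulate` at this config.

    Regenerates the same founder pools the simulator would draw (founder
    draws live on their own RNG stream) and applies :func:`founder_r2` —
    population values, not sample estimates.
    """
    rng_pool, *_ = _rngs(cfg)
    pools = _founder_pools(cfg, rng_pool)
    if not 0 <= block < len(pools):
        raise ValueError(f"block {block} out of range (0..{len(pools) - 1})")
    return founder_r2(pools[block])
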