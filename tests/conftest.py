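from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference.py importable

from ldknni import GenotypeMatrix, MISSING


def make_random_gm(
    seed: int, n_samples: int = 25, n_snps: int = 40, missing: float = 0.2
) -> GenotypeMatrix:
    """Unstructured random dosage matrix; every column keeps ≥1 observed entry."""
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    drop = rng.random(dos.shape) < missing
    dos[drop] = MISSING
    for j in np.flatnonzero((dos == MISSING).all(axis=0)):
        dos[0, j] = rng.integers(0, 3)
    return GenotypeMatrix(
        dosage=dos,
        samples=[f"s{i}" for i in range(n_samples)],
        snps=[f"m{j}" for j in range(n_snps)],
    )


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    return make_random_gm(11, 25, 40, 0.2)


@pytest.fixture
def block_sim():
    """Small block-LD simulation with truth for recovery checks."""
    from ldknni import SimConfig, simulate

    cfg = SimConfig(
        n_samples=120, n_snps=100, block_size=10, founder_pool=4,
        missing_rate=0.1, seed=7,
    )
    truth, obs = simulate(cfg)
    return cfg, truth, obs
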