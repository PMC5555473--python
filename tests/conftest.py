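"""Shared fixtures: hand-built toy pedigrees and small simulated datasets.

All simulation fixtures are generated at test time with fixed seeds; the
tiny dataset keeps the Gibbs sampler and dense oracles affordable, while
the reduced-scale scenario grid (session-scoped, built once) backs the
slower pattern assertions.
"""

import numpy as np
import pytest

from ssgp.pedigree import Pedigree
from ssgp.simulation import SimulationConfig, simulate_study


@pytest.fixture
def founder_pair_offspring():
    """Two unrelated founders and their child."""
    return Pedigree(
        ids=np.array(["S", "D", "X"]),
        sire=np.array([-1, -1, 0]),
        dam=np.array([-1, -1, 1]),
        generation=np.array([0, 0, 1]),
        sex=np.array(["M", "F", "F"]),
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Founders A,B; full sibs C,D; E = C x D (inbred, F=0.25)."""
    return Pedigree(
        ids=np.array(["A", "B", "C", "D", "E"]),
        sire=np.array([-1, -1, 0, 0, 2]),
        dam=np.array([-1, -1, 1, 1, 3]),
        generation=np.array([0, 0, 1, 1, 2]),
        sex=np.array(["M", "F", "M", "F", "M"]),
    )


@pytest.fixture
def six_id_pedigree():
    """Three founders, two G1, one G2: mixed genotyped/nongenotyped toy."""
    return Pedigree(
        ids=np.arange(1, 7),
        sire=np.array([-1, -1, -1, 0, 0, 3]),
        dam=np.array([-1, -1, -1, 1, 2, 4]),
        generation=np.array([0, 0, 0, 1, 1, 2]),
        sex=np.array(["M", "F", "F", "M", "F", "M"]),
    )


def random_pedigree(seed: int, n: int = 40) -> Pedigree:
    """Random generation-structured pedigree with occasional unknowns."""
    rng = np.random.default_rng(seed)
    n_founders = max(4, n // 5)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.array(["M", "F"] * ((n + 1) // 2))[:n]
    gen = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == "M")
        females = np.flatnonzero(sex[:i] == "F")
        if rng.random() > 0.1:
            sire[i] = rng.choice(males)
        if rng.random() > 0.1:
            dam[i] = rng.choice(females)
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        gen[i] = 1 + max((gen[p] for p in parents), default=0)
    return Pedigree(ids=np.arange(1, n + 1), sire=sire, dam=dam, generation=gen, sex=sex)


TINY_CONFIG = SimulationConfig(
    n_loci=20,
    n_chrom=2,
    qtl_per_chrom=2,
    n_base=40,
    n_dams=30,
    n_sires=5,
    n_generations=3,
    n_expansion_generations=2,
    pool_size=40,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """240-individual study: full structure, affordable for dense oracles."""
    return simulate_study(TINY_CONFIG, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    """Mid-size study (960 individuals) for metric-level checks."""
    cfg = SimulationConfig.reduced(n_dams=80, n_sires=8, pool_size=60)
    return simulate_study(cfg, seed=7)
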