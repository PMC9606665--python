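import numpy as np
import pytest

from kinvar import (
    Pedigree,
    SimulationConfig,
    build_A,
    simulate_population,
)


def random_pedigree(n: int, n_founders: int, rng: np.random.Generator) -> Pedigree:
    """Random valid pedigree: founders first, each later individual gets two
    distinct earlier parents (or one/none with small probability)."""
    records = [(str(i + 1), 0, 0) for i in range(n_founders)]
    for i in range(n_founders, n):
        u = rng.random()
        if u < 0.1:
            s = d = 0
        elif u < 0.2:
            s, d = rng.integers(1, i + 1), 0
        else:
            s, d = rng.choice(np.arange(1, i + 1), size=2, replace=False)
        records.append((str(i + 1), str(int(s)), str(int(d))))
    return Pedigree.from_records(records)


@pytest.fixture(scope="session")
def small_population():
    """~150-individual selected population with markers for matrix tests."""
    cfg = SimulationConfig(
        n_founder_males=15,
        n_founder_females=15,
        n_generations=3,
        n_markers=400,
        genotyped_generations=(2, 3),
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def model_population():
    """~300-individual population without markers for REML/BLUP tests."""
    cfg = SimulationConfig(
        n_founder_males=35,
        n_founder_females=35,
        n_generations=3,
        n_markers=0,
        seed=7,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def model_A(model_population):
    return build_A(model_population.pedigree)
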