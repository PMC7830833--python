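import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from riverepi import FourStateMatrix, SimConfig, simulate_dataset
from riverepi.msaflp import STATES


def random_four_state(rng, n_pops=3, n_per_pop=4, n_loci=10, p_missing=0.0):
    """IID four-state matrix with population labels (no structure)."""
    n = n_pops * n_per_pop
    states = rng.choice(list(STATES), size=(n, n_loci)).astype(object)
    if p_missing:
        mask = rng.random((n, n_loci)) < p_missing
        states[mask] = np.nan
    index = [f"p{k}_i{j}" for k in range(n_pops) for j in range(n_per_pop)]
    pops = pd.Series([f"p{k}" for k in range(n_pops) for _ in range(n_per_pop)],
                     index=index)
    df = pd.DataFrame(states, index=index,
                      columns=[f"L{j}" for j in range(n_loci)])
    return FourStateMatrix(df, pops)


def random_distance_matrix(rng, ids):
    """Random symmetric nonnegative zero-diagonal matrix."""
    n = len(ids)
    a = rng.random((n, n))
    a = a + a.T
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(a, ids=list(ids))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_four_state(rng):
    return random_four_state(rng)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic two-species riverscape shared across tests."""
    cfg = SimConfig(n_sites=6, n_individuals_per_site=8, n_epiloci=40,
                    n_snps=60, n_microsat_loci=5)
    return simulate_dataset(cfg, seed=7)
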