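import numpy as np
import pandas as pd
import pytest

from hegcor import (
    SimSpec, kinship_from_genotypes, simulate_founder_probs, simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-animal cohort with genotypes and kinship, shared across tests."""
    G = simulate_genotypes(SimSpec(n_individuals=400, n_markers=500, seed=11))
    K = kinship_from_genotypes(G)
    return G, K


@pytest.fixture(scope="session")
def founder_probs_small():
    """200 animals x 120 markers x 8 founders of simulated ancestry."""
    return simulate_founder_probs(200, n_markers=120, n_founders=8, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def covariate_frame():
    rng = np.random.default_rng(7)
    n = 300
    return pd.DataFrame({
        "age": rng.integers(100, 900, size=n).astype(float),
        "sex": rng.choice(["F", "M"], size=n),
        "generation": rng.choice(["G1", "G2", "G3"], size=n),
        "diet": rng.choice(["AL", "20CR", "40CR"], size=n),
    })
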