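import numpy as np
import pandas as pd
import pytest

from homeoscreen import GenotypeParams
from homeoscreen.simulate import simulate_genotype, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noise_free_params():
    return GenotypeParams(name="ideal", q_cv=0.0, qc_cv=0.0, meas_cv=0.0)


def make_screen(seed: int, n_hits: int = 3, n_def: int = 10, n_per: int = 10):
    """Screen with the first ``n_hits`` deficiencies fully blocked (h=0)."""
    rng = np.random.default_rng(seed)
    reference = GenotypeParams(name="ref")
    defs = [
        (
            f"Df{i:02d}",
            int(rng.integers(5, 51)),
            GenotypeParams(name=f"Df{i:02d}", compensation=0.0 if i < n_hits else 1.0),
        )
        for i in range(n_def)
    ]
    return simulate_screen(reference, defs, n_per, rng)


@pytest.fixture
def screen_tables():
    return make_screen(seed=7)


@pytest.fixture
def genotype_table():
    """One homeostatically intact genotype, 20 NMJs per PhTx state."""
    return simulate_genotype(
        GenotypeParams(name="wt"), 20, np.random.default_rng(1)
    )


def two_state_table(params: GenotypeParams, n: int, seed: int) -> pd.DataFrame:
    return simulate_genotype(params, n, np.random.default_rng(seed))
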