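import numpy as np
import pandas as pd
import pytest

from tucoda.composition import replace_zeros
from tucoda.simulate import CohortSimConfig, simulate_cohort

COMP_COLS = ["sleep_min", "sed_min", "lpa_min", "mvpa_min"]


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small but structured cohort: 12 participants per stratum, 5 days."""
    cfg = CohortSimConfig(seed=11, n_per_stratum=12, days_per_wave=5, n_zero_mvpa_days=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_valid_cohort(small_cohort) -> pd.DataFrame:
    """The same cohort restricted to valid days, zeros replaced."""
    df = small_cohort[small_cohort["valid"]].copy()
    df[COMP_COLS] = replace_zeros(df[COMP_COLS].to_numpy())
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_compositions(rng: np.random.Generator, n: int, d: int = 4) -> np.ndarray:
    """Strictly positive part vectors with realistic spread."""
    return np.exp(rng.normal(0.0, 1.0, size=(n, d))) * rng.uniform(10.0, 800.0, size=(n, d))
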