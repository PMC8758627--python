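import numpy as np
import pandas as pd
import pytest

from mtcnkit import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 1,000-individual cohort with default planted structure."""
    cfg = synthdata.SimulationConfig(
        n_individuals=1000, n_snps=200, n_mtsnps=60, seed=42)
    return synthdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """5,000-individual cohort for effect-recovery checks."""
    cfg = synthdata.SimulationConfig(
        n_individuals=5000, n_snps=120, n_mtsnps=60, seed=7)
    return synthdata.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def standardize(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)
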