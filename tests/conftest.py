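import numpy as np
import pandas as pd
import pytest

import lakegrowth as lg


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally complete study design."""
    return lg.SimulationConfig(
        n_lakes=8,
        n_species=2,
        years_per_lake=2,
        fish_per_survey=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(daily, thermal, scaler, truth, fish, masked) for the small design."""
    return lg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def tiny_survey():
    """One hand-built survey of aged fish."""
    rng = np.random.default_rng(42)
    n = 60
    ages = rng.integers(1, 9, size=n).astype(float)
    params = lg.BiphasicParams(alpha=2.0, beta1=4.0, beta2=1.5, amat=3.0)
    lengths = np.exp(np.log(params.mean(ages)) + rng.normal(0, 0.1, n))
    return pd.DataFrame(
        {
            "fish_id": np.arange(n),
            "species": "species_A",
            "lake_id": "lake_000",
            "year": 2015,
            "length_cm": lengths,
            "age_yr": ages,
            "structure": "otolith",
            "aged_flag": True,
        }
    )
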