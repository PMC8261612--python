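import logging

import numpy as np
import pandas as pd
import pytest

from abaccess.synthetic import SyntheticConfig, TrueParameters, generate_dataset

# the grade-merge warnings are expected noise in cross-validation fixtures
logging.getLogger("abaccess.model").setLevel(logging.ERROR)


def small_config(seed=7, **kw):
    base = dict(
        n_states=8,
        counties_per_state=(12, 18),
        tracts_per_county=(2, 5),
        grid_extent=300.0,
        facility_count=25,
        nonreporting_fraction=0.25,
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def recovery_config(seed, **kw):
    """~1500 fully reporting counties in 27 states, mirroring the modelled
    study population."""
    base = dict(
        n_states=27,
        counties_per_state=(50, 62),
        tracts_per_county=(2, 6),
        grid_extent=1100.0,
        facility_count=160,
        nonreporting_fraction=0.0,
        suppression_limit_by_state={},
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def midsize_dataset():
    """One ~1500-county fully observed dataset with the default truth."""
    return generate_dataset(recovery_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_counties():
    """Four counties in two states, hand-checkable."""
    return pd.DataFrame(
        {
            "county_id": [0, 1, 2, 3],
            "state_id": ["A", "A", "B", "B"],
            "pop_f1544": [1000.0, 2000.0, 1500.0, 500.0],
            "abortions": [10.0, 30.0, 12.0, np.nan],
            "x": [0.0, 1.0, 0.0, 1.0],
            "y": [0.0, 0.0, 1.0, 1.0],
        }
    )
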