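import numpy as np
import pandas as pd
import pytest

from sharedarch import syndata
from sharedarch.tables import PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Continuous-item cohort with planted [0.25, 0.15], no missingness."""
    config = syndata.CohortConfig(
        n_subjects=1500, canonical_rhos=(0.25, 0.15),
        item_thresholds=None, missing_rate=0.0, seed=42)
    return syndata.generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    config = syndata.CohortConfig(
        n_subjects=800, canonical_rhos=(), n_latents=0,
        item_thresholds=None, missing_rate=0.0, seed=7)
    return syndata.generate_cohort(config)


@pytest.fixture
def toy_table(rng):
    df = pd.DataFrame({
        "x": rng.normal(size=30),
        "y": rng.normal(size=30),
        "z": rng.normal(size=30),
    }, index=pd.RangeIndex(30, name="subject"))
    return PhenotypeTable(df)
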