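import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fraxbuild import FractureRecord, default_config


def make_record(**overrides) -> FractureRecord:
    """A valid hip-fracture record with per-field overrides."""
    base = dict(
        person_id="P001",
        event_date=dt.date(2013, 6, 1),
        age=72,
        sex="female",
        site="hip",
        icd10="S72.0",
        trauma_energy="low",
        pathological=0,
        resident=1,
        care_source="inpatient",
        region="Ararat",
    )
    base.update(overrides)
    return FractureRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast generator tests."""
    return default_config(seed=7, scale=0.15)


@pytest.fixture
def single_band_population():
    """One open band [50, inf) per sex, matching the study's 50+ totals."""
    return pd.DataFrame(
        {
            "region": ["all", "all"],
            "sex": ["female", "male"],
            "age_lo": [50, 50],
            "age_hi": [np.nan, np.nan],
            "person_years": [55_838.0, 45_871.0],
        }
    )
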