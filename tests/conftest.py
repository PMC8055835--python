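import numpy as np
import pytest

from psmcure import (
    EconomicInputs,
    SurvivalDataset,
    default_calibration,
    generate_ipd,
)


@pytest.fixture(scope="session")
def calibration():
    """Default arm specifications and life table."""
    return default_calibration()


@pytest.fixture(scope="session")
def trial_2k(calibration):
    """A 2,000/arm dataset from the default calibration (shared, read-only)."""
    spec_i, spec_c, lt = default_calibration((2000, 2000))
    return generate_ipd([spec_i, spec_c], lt, seed=42), lt


@pytest.fixture(scope="session")
def econ():
    return EconomicInputs.default()


@pytest.fixture()
def three_deaths():
    """Three uncensored deaths at t = 1, 2, 3 (hand-checkable KM)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "patient_id": [0, 1, 2],
            "arm": "X",
            "os_time": [1.0, 2.0, 3.0],
            "os_event": [1, 1, 1],
            "pfs_time": [1.0, 2.0, 3.0],
            "pfs_event": [1, 1, 1],
        }
    )
    return SurvivalDataset(df)
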