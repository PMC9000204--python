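import numpy as np
import pandas as pd
import pytest

from he4align import multicenter_calibration
from he4align.io import series_from_wide


@pytest.fixture(scope="session")
def calibration_table() -> pd.DataFrame:
    """The six-laboratory HE4 calibration dilution series (wide table)."""
    return multicenter_calibration()


@pytest.fixture(scope="session")
def calibration_series(calibration_table):
    """One CalibrationSeries per test laboratory, lab1 as reference."""
    return {
        lab: series_from_wide(calibration_table, "lab1", lab)
        for lab in ("lab2", "lab3", "lab4", "lab5", "lab6")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
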