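import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirscreen.screen_core import WELL_COLUMNS

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_plate(
    plate_id: str,
    control_ratios,
    test_ratios,
    firefly: float = 1000.0,
    reporter_id: str = "utr-001",
    test_mirna: str = "mir-0001",
):
    """Build a one-plate well table from desired raw Renilla/firefly ratios."""
    rows = []
    for i, ratio in enumerate(control_ratios, start=1):
        rows.append(
            (plate_id, f"C{i:02d}", "control", "empty_vector", reporter_id, i,
             firefly, firefly * ratio)
        )
    for i, ratio in enumerate(test_ratios, start=1):
        rows.append(
            (plate_id, f"T{i:02d}", "test", test_mirna, reporter_id, i,
             firefly, firefly * ratio)
        )
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


@pytest.fixture
def simple_plate():
    return make_plate("plate-001", control_ratios=[2.0, 2.0], test_ratios=[1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
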