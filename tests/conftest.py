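import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from peonychill import HourlyTemperatureSeries

settings.register_profile("stable", derandomize=True, max_examples=60)
settings.load_profile("stable")


@pytest.fixture
def make_constant_series():
    """Factory: n hours at a fixed temperature from a fixed start stamp."""

    def _make(temp_c: float, hours: int, start: str = "2012-12-01 00:00") -> HourlyTemperatureSeries:
        idx = pd.date_range(start, periods=hours, freq="h")
        return HourlyTemperatureSeries(pd.Series(np.full(hours, float(temp_c)), index=idx))

    return _make


@pytest.fixture
def make_series_from_daily_means():
    """Factory: one flat reading per hour so each date's mean is as requested."""

    def _make(means, start: str = "2012-12-01") -> HourlyTemperatureSeries:
        values, stamps = [], []
        day0 = pd.Timestamp(start)
        for d, mean in enumerate(means):
            for h in range(24):
                stamps.append(day0 + pd.Timedelta(days=d, hours=h))
                values.append(float(mean))
        return HourlyTemperatureSeries(pd.Series(values, index=pd.DatetimeIndex(stamps)))

    return _make


@pytest.fixture
def small_morpho():
    """Three treatments along a saturating dose ladder, two indices."""
    rows = []
    specs = {
        "T1": {"FBP": 40.0, "NOF": 0.0},
        "T2": {"FBP": 96.0, "NOF": 2.0},
        "T3": {"FBP": 100.0, "NOF": 3.0},
    }
    for tid, idx_vals in specs.items():
        for code, value in idx_vals.items():
            for rep in (1, 2, 3):
                rows.append(
                    {"treatment_id": tid, "index_code": code, "replicate": rep, "value": value}
                )
    return pd.DataFrame(rows)
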