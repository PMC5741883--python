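"""Chill-hour and chill-unit accumulation models.

Two classical winter-chill dose models for bud dormancy release:

* **Chill hours (CH)** — every hour with air temperature inside an
  effective band (default 0–7.2 °C, endpoints included) contributes one
  hour of chill; hours outside the band contribute nothing.
* **Chill units (CU)** — a temperature-weighted hour: weight 1 below
  0 °C, declining linearly as ``-0.0605 * T + 1`` between 0 and 10 °C
  (endpoints in the linear segment), and 0 above 10 °C.

Accumulation is a plain sum of per-hour weights over a half-open time
window ``[start, end)`` of hourly readings, which makes totals additive
over any partition of the window and avoids double counting at transfer
instants.  Refrigerated-storage treatments at a constant temperature
admit the closed form ``hours * weight(T)``.

Chill totals are kept at full floating precision internally;
:func:`format_chill` applies the 2-decimal half-up rounding used for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import (
    ChillDataError,
    GapError,
    StartDateNotFoundError,
    WindowRangeError,
)

__all__ = [
    "HourlyTemperatureSeries",
    "ChillHourModel",
    "ChillUnitModel",
    "AccumulationWindow",
    "ch_weight",
    "cu_weight",
    "hourly_accumulate",
    "constant_accumulate",
    "daily_means",
    "detect_start_date",
    "format_chill",
]

TEMP_MIN, TEMP_MAX = -30.0, 50.0  # plausible air-temperature range (°C)


def format_chill(total: float, decimals: int = 2) -> float:
    """Round a chill total half-up to `decimals` places (presentation only)."""
    q = Decimal(1).scaleb(-decimals)
    # pre-round at 9 decimals so float artefacts (e.g. 738.3599999...) do
    # not leak through the Decimal conversion
    return float(Decimal(f"{total:.9f}").quantize(q, rounding=ROUND_HALF_UP))


class HourlyTemperatureSeries:
    """One winter of hourly air-temperature readings.

    Parameters
    ----------
    temps
        Temperatures in °C indexed by naive local timestamps at exact
        hourly resolution.  Timestamps must be strictly increasing and
        on the hour; values must be finite and inside [−30, 50] °C.
    season_label
        Free-text label, e.g. ``"2012-2013"``.

    Missing hours between the first and last stamp are detected at
    construction and exposed as :attr:`gaps`; they are never silently
    filled.
    """

    def __init__(self, temps: pd.Series, season_label: str = ""):
        if not isinstance(temps, pd.Series):
            raise TypeError("temps must be a pandas Series with a DatetimeIndex")
        if len(temps) == 0:
            raise ChillDataError("empty temperature series")
        idx = pd.DatetimeIndex(temps.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ChillDataError("timestamps must be strictly increasing and unique")
        if ((idx.minute != 0) | (idx.second != 0) | (idx.microsecond != 0)).any():
            raise ChillDataError("timestamps must be at exact hourly resolution")
        values = np.asarray(temps.to_numpy(), dtype=float)
        if not np.isfinite(values).all():
            raise ChillDataError("non-finite temperature reading")
        bad = (values < TEMP_MIN) | (values > TEMP_MAX)
        if bad.any():
            raise ChillDataError(
                f"{int(bad.sum())} reading(s) outside [{TEMP_MIN}, {TEMP_MAX}] °C "
                "rejected as sensor error"
            )
        idx = idx.rename("timestamp")
        self.temps = pd.Series(values, index=idx, name="temp_c")
        self.season_label = season_label
        expected = pd.date_range(idx[0], idx[-1], freq="h")
        self.gaps = expected.difference(idx)

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        season_label: str = "",
    ) -> "HourlyTemperatureSeries":
        """Build from an iterable of ``(timestamp, temp_c)`` pairs."""
        stamps, temps = zip(*records)
        return cls(pd.Series(list(temps), index=pd.DatetimeIndex(stamps)), season_label)

    @property
    def start(self) -> pd.Timestamp:
        return self.temps.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.temps.index[-1]

    def __len__(self) -> int:
        return len(self.temps)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HourlyTemperatureSeries({self.season_label!r}, "
            f"{self.start} .. {self.end}, n={len(self)}, gaps={len(self.gaps)})"
        )


@dataclass(frozen=True)
class ChillHourModel:
    """Indicator weighting: 1 inside [t_low, t_high] (inclusive), else 0."""

    t_low: float = 0.0
    t_high: float = 7.2
    inclusive_bounds: bool = True
    unit: str = field(default="CH", init=False)

    def __post_init__(self):
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")

    def weight(self, t):
        t = np.asarray(t, dtype=float)
        if not np.isfinite(t).all():
            raise ChillDataError("non-finite temperature")
        if self.inclusive_bounds:
            w = (t >= self.t_low) & (t <= self.t_high)
        else:
            w = (t > self.t_low) & (t < self.t_high)
        return w.astype(float) if w.ndim else float(w)


@dataclass(frozen=True)
class ChillUnitModel:
    """Piecewise-linear weighting: 1 below t_zero, ``slope*t + intercept``
    on [t_zero, t_max], 0 above t_max."""

    slope: float = -0.0605
    intercept: float = 1.0
    t_zero: float = 0.0
    t_max: float = 10.0
    unit: str = field(default="CU", init=False)

    def weight(self, t):
        t = np.asarray(t, dtype=float)
        if not np.isfinite(t).all():
            raise ChillDataError("non-finite temperature")
        linear = self.slope * t + self.intercept
        w = np.where(t < self.t_zero, 1.0, np.where(t > self.t_max, 0.0, linear))
        return w if w.ndim else float(w)


ChillModel = Union[ChillHourModel, ChillUnitModel]


def ch_weight(t: float, model: ChillHourModel | None = None) -> float:
    """Chill-hour weight of one temperature reading (0 or 1)."""
    return (model or ChillHourModel()).weight(t)


def cu_weight(t: float, model: ChillUnitModel | None = None) -> float:
    """Chill-unit weight of one temperature reading (in [0, 1])."""
    return (model or ChillUnitModel()).weight(t)


@dataclass(frozen=True)
class AccumulationWindow:
    """Half-open accumulation window ``[start, end)`` on hourly stamps."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError("window start must precede end")


def _as_window(window) -> AccumulationWindow:
    if isinstance(window, AccumulationWindow):
        return window
    start, end = window
    return AccumulationWindow(pd.Timestamp(start), pd.Timestamp(end))


def hourly_accumulate(
    series: HourlyTemperatureSeries,
    window,
    model: ChillModel,
    *,
    interpolate_gaps: bool = False,
    max_gap_hours: int = 3,
) -> float:
    """Sum per-hour chill weights over records with ``start <= t < end``.

    Gaps inside the window raise :class:`GapError` listing the missing
    hours.  With ``interpolate_gaps=True``, runs of at most
    ``max_gap_hours`` missing hours are filled by linear interpolation
    of temperature before weighting (longer runs still raise).
    """
    win = _as_window(window)
    if win.start < series.start or win.end > series.end + pd.Timedelta(hours=1):
        raise WindowRangeError(
            f"window [{win.start}, {win.end}) outside series span "
            f"[{series.start}, {series.end}]"
        )
    expected = pd.date_range(win.start, win.end, freq="h", inclusive="left")
    present = series.temps.reindex(expected)
    missing = expected[present.isna().to_numpy()]
    if len(missing):
        if not interpolate_gaps:
            raise GapError(missing)
        runs = _gap_run_lengths(missing)
        if max(runs) > max_gap_hours:
            raise GapError(missing)
        present = present.interpolate(method="time", limit_area="inside")
        if present.isna().any():
            raise GapError(expected[present.isna().to_numpy()])
    return float(np.sum(model.weight(present.to_numpy())))


def _gap_run_lengths(missing: pd.DatetimeIndex) -> list[int]:
    runs, current = [], 1
    for prev, cur in zip(missing[:-1], missing[1:]):
        if cur - prev == pd.Timedelta(hours=1):
            current += 1
        else:
            runs.append(current)
            current = 1
    runs.append(current)
    return runs


def constant_accumulate(t_const: float, hours: float, model: ChillModel) -> float:
    """Chill total of `hours` hours at a constant temperature.

    Closed form for refrigerated storage: ``hours * weight(t_const)``.
    Equals :func:`hourly_accumulate` on a constant synthetic series of
    the same length.
    """
    if hours < 0:
        raise ValueError("hours must be non-negative")
    return float(hours) * float(model.weight(t_const))


def daily_means(series: HourlyTemperatureSeries) -> pd.DataFrame:
    """Per-calendar-date mean temperature.

    Returns a frame indexed by date with columns ``mean_c``, ``n_hours``
    and ``complete`` (True when all 24 hourly readings are present).
    """
    grouped = series.temps.groupby(series.temps.index.date)
    out = grouped.agg(mean_c="mean", n_hours="size")
    out.index = pd.Index([pd.Timestamp(d) for d in out.index], name="date")
    out["complete"] = out["n_hours"] == 24
    return out


def detect_start_date(
    series: HourlyTemperatureSeries,
    threshold: float,
    persistence_days: int = 3,
) -> pd.Timestamp:
    """First date whose daily mean stays strictly below `threshold`.

    The start of chill accounting is the first calendar date ``d`` such
    that the daily means on ``d`` and the following ``persistence_days - 1``
    dates are all strictly below `threshold` ("steadily passed" the
    threshold).  Returns midnight of that date.
    """
    if persistence_days < 1:
        raise ValueError("persistence_days must be >= 1")
    by_day = daily_means(series)
    means = by_day["mean_c"].to_numpy()
    dates = by_day.index
    below = means < threshold
    n = persistence_days
    for i in range(len(below) - n + 1):
        if below[i : i + n].all():
            return pd.Timestamp(dates[i]).normalize()
    raise StartDateNotFoundError(
        f"no run of {n} day(s) with mean below {threshold} °C in "
        f"{series.season_label or 'series'}"
    )
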