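"""Chilling-requirement (CR) estimation from chilling-dose experiments.

A CR experiment applies a ladder of chilling doses — either natural
outdoor exposure ended on successive transfer dates, or refrigerated
storage of increasing duration — and scores each treatment's subsequent
sprouting/flowering performance.  The CR is bracketed between the
largest dose that performed inadequately and the smallest that
performed adequately.  Brackets from independent experiments sharing a
chill unit can be intersected.

The same chill model is then used "in reverse": given the CR, the first
sampling checkpoint in a winter whose accumulated chill reaches the CR
marks the CR-fulfillment date, and two winters can be compared by the
calendar delay between their fulfillment dates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chill_models import (
    ChillModel,
    HourlyTemperatureSeries,
    constant_accumulate,
    detect_start_date,
    hourly_accumulate,
)
from .errors import ConfigError, EstimationError, UndefinedDelayError, UnitMismatchError

__all__ = [
    "Treatment",
    "CRBracket",
    "treatment_accumulation",
    "adequacy_labels",
    "DEFAULT_ADEQUACY_RULES",
    "bracket_from_outcomes",
    "intersect_brackets",
    "composite_rank",
    "estimate_fulfillment",
    "fulfillment_delay",
]


@dataclass(frozen=True)
class Treatment:
    """One chilling treatment: natural exposure or refrigerated storage.

    ``chill_end`` is the instant the plants leave the cold (transfer
    into the glasshouse / out of storage).  ``chill_start`` is the start
    of storage for artificial treatments; for natural treatments it is
    usually None and supplied by a start-date rule at accumulation time.
    ``storage_temp`` (°C) is required for, and only for, artificial mode.
    """

    id: str
    mode: str  # "natural" | "artificial"
    chill_end: pd.Timestamp
    chill_start: Optional[pd.Timestamp] = None
    storage_temp: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("natural", "artificial"):
            raise ConfigError(f"unknown treatment mode {self.mode!r}")
        object.__setattr__(self, "chill_end", pd.Timestamp(self.chill_end))
        if self.chill_start is not None:
            object.__setattr__(self, "chill_start", pd.Timestamp(self.chill_start))
            if self.chill_start > self.chill_end:
                raise ConfigError(f"{self.id}: chill_start after chill_end")
        if self.mode == "artificial":
            if self.storage_temp is None:
                raise ConfigError(f"{self.id}: artificial treatment needs storage_temp")
            if self.chill_start is None:
                raise ConfigError(f"{self.id}: artificial treatment needs chill_start")
        elif self.storage_temp is not None:
            raise ConfigError(f"{self.id}: storage_temp only valid for artificial mode")


def treatment_accumulation(
    treatment: Treatment,
    series: Optional[HourlyTemperatureSeries],
    model: ChillModel,
    *,
    start: Optional[pd.Timestamp] = None,
    start_threshold: Optional[float] = None,
    persistence_days: int = 3,
) -> float:
    """Chill total acquired by one treatment.

    Natural mode sums hourly weights from the chill start (given
    explicitly via `start`, or detected from the series with
    `start_threshold`) to the transfer instant; a transfer before the
    start date accumulates 0 (blank control).  Artificial mode uses the
    constant-temperature closed form over the whole hours of storage.
    """
    if treatment.mode == "artificial":
        hours = (treatment.chill_end - treatment.chill_start) / pd.Timedelta(hours=1)
        return constant_accumulate(treatment.storage_temp, round(hours), model)
    if series is None:
        raise EstimationError(f"{treatment.id}: natural treatment requires a temperature series")
    if start is None:
        if treatment.chill_start is not None:
            start = treatment.chill_start
        elif start_threshold is not None:
            start = detect_start_date(series, start_threshold, persistence_days)
        else:
            raise ConfigError("natural treatment needs `start` or `start_threshold`")
    start = pd.Timestamp(start)
    if treatment.chill_end <= start:
        return 0.0
    return hourly_accumulate(series, (start, treatment.chill_end), model)


# ---------------------------------------------------------------------------
# morphology-based adequacy and ranking
# ---------------------------------------------------------------------------

#: Default adequacy rule: essentially complete budbreak and at least one
#: opening flower.  Each entry maps an index code to (operator, threshold)
#: applied to the treatment mean over replicates.
DEFAULT_ADEQUACY_RULES: dict[str, tuple[str, float]] = {
    "FBP": (">=", 95.0),
    "NOF": (">", 0.0),
}

_OPS = {
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
}


def adequacy_labels(
    morpho: pd.DataFrame,
    rules: Mapping[str, tuple[str, float]] | None = None,
) -> dict[str, str]:
    """Label each treatment ``adequate``/``inadequate`` by threshold rules.

    `morpho` is long-format with columns ``treatment_id``, ``index_code``,
    ``replicate``, ``value``.  A treatment is adequate when every rule
    holds for its replicate-mean value of that index.
    """
    rules = dict(rules if rules is not None else DEFAULT_ADEQUACY_RULES)
    if morpho is None or len(morpho) == 0:
        raise ConfigError("empty morphology table")
    required = {"treatment_id", "index_code", "value"}
    if not required.issubset(morpho.columns):
        raise ConfigError(f"morphology table needs columns {sorted(required)}")
    present = set(morpho["index_code"].unique())
    missing = [ix for ix in rules if ix not in present]
    if missing:
        raise ConfigError(f"adequacy rule references absent index(es): {missing}")
    means = (
        morpho.groupby(["treatment_id", "index_code"])["value"].mean().unstack("index_code")
    )
    labels = {}
    for tid, row in means.iterrows():
        ok = True
        for ix, (op, threshold) in rules.items():
            if op not in _OPS:
                raise ConfigError(f"unknown operator {op!r} in adequacy rule")
            if not _OPS[op](row[ix], threshold):
                ok = False
                break
        labels[str(tid)] = "adequate" if ok else "inadequate"
    return labels


@dataclass(frozen=True)
class CRBracket:
    """Interval estimate of the chilling requirement, in model units."""

    lower: float
    upper: float
    model: str = "CH"
    lower_open: bool = True
    upper_open: bool = False

    def __post_init__(self):
        if self.lower > self.upper:
            raise EstimationError(
                f"inconsistent bracket: lower {self.lower} > upper {self.upper}"
            )

    def contains(self, x: float) -> bool:
        lo = x > self.lower if self.lower_open else x >= self.lower
        hi = x < self.upper if self.upper_open else x <= self.upper
        return lo and hi

    def __str__(self) -> str:
        lo = "(" if self.lower_open else "["
        hi = ")" if self.upper_open else "]"
        return f"{lo}{self.lower:.2f}, {self.upper:.2f}{hi} {self.model}"


def bracket_from_outcomes(
    accumulations: Mapping[str, float],
    labels: Mapping[str, str],
    model: str = "CH",
) -> CRBracket:
    """CR bracket from per-treatment chill doses and adequacy labels.

    Lower bound (open) = largest dose among inadequate treatments;
    upper bound (closed) = smallest dose among adequate treatments.
    With no inadequate treatment the lower bound is 0 (closed).
    """
    adequate = [accumulations[t] for t, lab in labels.items() if lab == "adequate"]
    inadequate = [accumulations[t] for t, lab in labels.items() if lab == "inadequate"]
    if not adequate:
        raise EstimationError("CR exceeds maximum applied chill (no adequate treatment)")
    upper = min(adequate)
    if inadequate:
        lower, lower_open = max(inadequate), True
    else:
        lower, lower_open = 0.0, False
    return CRBracket(lower, upper, model=model, lower_open=lower_open, upper_open=False)


def intersect_brackets(a: CRBracket, b: CRBracket) -> Optional[CRBracket]:
    """Intersection of two CR brackets; None when they do not overlap."""
    if a.model != b.model:
        raise UnitMismatchError(f"cannot intersect {a.model} with {b.model} brackets")
    if a.lower > b.lower or (a.lower == b.lower and a.lower_open):
        lower, lower_open = a.lower, a.lower_open
    else:
        lower, lower_open = b.lower, b.lower_open
    if a.upper < b.upper or (a.upper == b.upper and a.upper_open):
        upper, upper_open = a.upper, a.upper_open
    else:
        upper, upper_open = b.upper, b.upper_open
    if lower > upper or (lower == upper and (lower_open or upper_open)):
        return None
    return CRBracket(lower, upper, model=a.model, lower_open=lower_open, upper_open=upper_open)


def composite_rank(
    morpho: pd.DataFrame,
    directions: Mapping[str, bool],
    weights: Mapping[str, float] | None = None,
    accumulations: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Rank treatments by a weighted mean of min–max-scaled index means.

    Each index's treatment means are min–max scaled to [0, 1] across
    treatments and flipped for lower-is-better indices (`directions`
    maps index code to higher-is-better).  The composite score is the
    weighted mean over indices (uniform weights by default).  Ties are
    broken toward lower chill accumulation when `accumulations` is
    given.  Constant indices carry no ranking information and are
    dropped with a warning.

    Returns a frame indexed by treatment with ``score`` and ``rank``
    (rank 1 = optimal).
    """
    if morpho is None or len(morpho) == 0:
        raise ConfigError("empty morphology table")
    means = (
        morpho.groupby(["treatment_id", "index_code"])["value"].mean().unstack("index_code")
    )
    unknown = [c for c in means.columns if c not in directions]
    if unknown:
        raise ConfigError(f"no direction registered for index(es): {unknown}")
    if weights is not None:
        w = pd.Series({c: weights.get(c, 0.0) for c in means.columns}, dtype=float)
        if (w < 0).any():
            raise ConfigError("weights must be non-negative")
        if not (w > 0).any():
            raise ConfigError("at least one weight must be positive")
    else:
        w = pd.Series(1.0, index=means.columns)

    scaled = {}
    for col in means.columns:
        lo, hi = means[col].min(), means[col].max()
        if math.isclose(lo, hi):
            warnings.warn(f"index {col} constant across treatments; dropped from ranking")
            continue
        s = (means[col] - lo) / (hi - lo)
        scaled[col] = s if directions[col] else 1.0 - s
    if not scaled:
        score = pd.Series(0.0, index=means.index)
    else:
        scaled_df = pd.DataFrame(scaled)
        wv = w[scaled_df.columns]
        score = scaled_df.mul(wv, axis=1).sum(axis=1) / wv.sum()

    out = pd.DataFrame({"score": score})
    if accumulations is not None:
        out["chill"] = [accumulations.get(t, np.inf) for t in out.index]
    else:
        out["chill"] = np.arange(len(out), dtype=float)  # stable fallback tie-break
    out = out.sort_values(["score", "chill"], ascending=[False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out.drop(columns="chill")


# ---------------------------------------------------------------------------
# reverse use: CR-fulfillment period across winters
# ---------------------------------------------------------------------------


def _as_checkpoints(checkpoints) -> pd.Series:
    cp = pd.Series(checkpoints).astype(float)
    cp.index = pd.DatetimeIndex(cp.index)
    if len(cp) == 0:
        raise EstimationError("empty checkpoint series")
    cp = cp.sort_index()
    if (np.diff(cp.to_numpy()) < 0).any():
        raise EstimationError("checkpoint accumulations must be non-decreasing")
    return cp


def estimate_fulfillment(checkpoints, cr: float) -> Optional[pd.Timestamp]:
    """Earliest checkpoint date whose accumulated chill reaches `cr`.

    `checkpoints` maps dates to accumulated chill (any mapping or pandas
    Series).  Returns None when the winter never reaches `cr`.
    """
    if cr < 0:
        raise ValueError("cr must be non-negative")
    cp = _as_checkpoints(checkpoints)
    hit = cp[cp >= cr]
    return None if hit.empty else pd.Timestamp(hit.index[0])


def _season_day(date: pd.Timestamp) -> int:
    """Day offset within a July-to-June winter cycle (for cross-year alignment)."""
    date = pd.Timestamp(date)
    anchor_year = date.year if date.month >= 7 else date.year - 1
    return (date - pd.Timestamp(anchor_year, 7, 1)).days


def fulfillment_delay(checkpoints_a, checkpoints_b, cr: float) -> tuple[int, int]:
    """Delay of winter B's CR fulfillment relative to winter A's.

    Dates are aligned on their position within each winter (July-June
    cycle) so that winters from different years compare by calendar
    month-day.  Returns ``(days, weeks)`` where weeks is days/7 rounded
    to the nearest integer; positive values mean B fulfills later.
    """
    date_a = estimate_fulfillment(checkpoints_a, cr)
    date_b = estimate_fulfillment(checkpoints_b, cr)
    if date_a is None or date_b is None:
        which = [w for w, d in (("A", date_a), ("B", date_b)) if d is None]
        raise UndefinedDelayError(f"winter(s) {', '.join(which)} never reach {cr} units")
    days = _season_day(date_b) - _season_day(date_a)
    return days, int(round(days / 7))
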