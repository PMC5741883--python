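"""Cross-winter congruence of short expression time courses.

A gene sampled at the same six calendar checkpoints in two winters gives
two six-point profiles.  The profiles are compared by Pearson
correlation at integer checkpoint lags: a gene whose seasonal program
simply ran late in the second winter correlates poorly at lag 0 but
strongly once the second profile is shifted back.  The best-lag result
is classified into three congruence types (shifted-similar, partially
similar, dissimilar), and a shifted-similar gene whose shift matches the
winter's CR-fulfillment delay — to within one checkpoint interval — is
flagged CR-congruent.

With only six checkpoints a lag scan is inherently coarse: the minimum
overlap is held at 3 points (Pearson r is undefined below 2 and
unstable at 2) and the maximum lag at ``length - 3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateProfileError

__all__ = [
    "CheckpointProfile",
    "LagResult",
    "CongruenceThresholds",
    "CongruenceReport",
    "best_lag",
    "classify_congruence",
    "congruence_with_fulfillment",
]


@dataclass(frozen=True)
class CheckpointProfile:
    """One gene's ordered expression values over a winter's checkpoints."""

    gene_id: str
    winter: str
    values: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if not np.isfinite(vals).all():
            raise ConfigError(f"{self.gene_id}/{self.winter}: non-finite profile value")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class LagResult:
    """Outcome of a lagged-correlation scan between two profiles.

    A positive ``best_lag`` means the second profile is delayed
    relative to the first by that many checkpoint steps.
    """

    best_lag: int
    r_zero: float
    r_best: float
    n_overlap: int


def _values(profile) -> np.ndarray:
    if isinstance(profile, CheckpointProfile):
        return np.asarray(profile.values, dtype=float)
    return np.asarray(profile, dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan  # constant overlap: correlation undefined, lag skipped
    return float(stats.pearsonr(x, y).statistic)


def best_lag(profile_a, profile_b, max_lag: int = 2) -> LagResult:
    """Scan integer lags for the best Pearson alignment of two profiles.

    For lag L the overlapping pairs are ``a[i] vs b[i + L]``, so a
    positive best lag means profile B is delayed relative to A.  Ties
    are broken toward the smaller absolute lag, then toward the negative
    lag.  Lags whose overlap is constant in either profile are skipped;
    if every lag is skipped the profiles are degenerate.
    """
    a, b = _values(profile_a), _values(profile_b)
    n = len(a)
    if len(b) != n:
        raise ConfigError("profiles must have the same length")
    if not 0 <= max_lag <= n - 3:
        raise ConfigError(f"max_lag must be in [0, {n - 3}] for {n}-point profiles")

    candidates = []  # (r, |lag|, lag) for valid lags
    r_zero = np.nan
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        r = _pearson(x, y)
        if lag == 0:
            r_zero = r
        if not np.isnan(r):
            candidates.append((r, lag, len(x)))
    if not candidates:
        raise DegenerateProfileError("constant overlap at every lag")
    # max r; ties (within float tolerance) -> smaller |lag|, then the negative one
    tol = 1e-9
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[0] > best[0] + tol:
            best = cand
        elif abs(cand[0] - best[0]) <= tol and (-abs(cand[1]), -np.sign(cand[1])) > (
            -abs(best[1]), -np.sign(best[1])
        ):
            best = cand
    return LagResult(best_lag=int(best[1]), r_zero=r_zero, r_best=float(best[0]), n_overlap=int(best[2]))


@dataclass(frozen=True)
class CongruenceThresholds:
    """Numeric thresholds behind the verbal congruence typing.

    ``r_high``: correlation needed (at the best lag) to call two
    profiles the same program; ``r_mid``: correlation for partial
    similarity; ``gain``: improvement of r_best over r_zero required as
    evidence that the shift is real.
    """

    r_high: float = 0.8
    r_mid: float = 0.5
    gain: float = 0.2


def classify_congruence(
    result: LagResult,
    thresholds: CongruenceThresholds | None = None,
) -> str:
    """Type a lag result: shifted_similar / partially_similar / dissimilar.

    ``shifted_similar`` needs a non-zero best lag, a high correlation at
    that lag, and a material gain over the lag-0 correlation; otherwise
    ``partially_similar`` when either correlation is at least moderate;
    otherwise ``dissimilar``.
    """
    th = thresholds or CongruenceThresholds()
    gain_ok = np.isnan(result.r_zero) or (result.r_best - result.r_zero) >= th.gain
    if abs(result.best_lag) >= 1 and result.r_best >= th.r_high and gain_ok:
        return "shifted_similar"
    r_max = np.nanmax([result.r_zero, result.r_best])
    if not np.isnan(r_max) and r_max >= th.r_mid:
        return "partially_similar"
    return "dissimilar"


@dataclass(frozen=True)
class CongruenceReport:
    """Agreement between an expression shift and the CR-fulfillment delay."""

    gene_shift_days: Optional[float]
    fulfillment_delay_days: Optional[float]
    checkpoint_spacing_days: float
    congruence_type: str
    congruent: Optional[bool]  # None when the delay is not evaluable


def congruence_with_fulfillment(
    result: LagResult,
    fulfillment_delay_days: Optional[float],
    checkpoint_spacing_days: float,
    thresholds: CongruenceThresholds | None = None,
) -> CongruenceReport:
    """Flag a gene whose expression shift matches the CR-fulfillment delay.

    The gene is CR-congruent when it classifies as shifted-similar and
    its shift, converted to days via the (median) checkpoint spacing,
    agrees with the fulfillment delay to within one checkpoint interval.
    A fulfillment delay of None (winter never fulfilled) propagates as
    not-evaluable (``congruent=None``).
    """
    if checkpoint_spacing_days <= 0:
        raise ConfigError("checkpoint_spacing_days must be positive")
    ctype = classify_congruence(result, thresholds)
    shift_days = result.best_lag * checkpoint_spacing_days
    if fulfillment_delay_days is None:
        return CongruenceReport(shift_days, None, checkpoint_spacing_days, ctype, None)
    congruent = (
        ctype == "shifted_similar"
        and abs(shift_days - fulfillment_delay_days) <= checkpoint_spacing_days
    )
    return CongruenceReport(
        gene_shift_days=shift_days,
        fulfillment_delay_days=float(fulfillment_delay_days),
        checkpoint_spacing_days=float(checkpoint_spacing_days),
        congruence_type=ctype,
        congruent=congruent,
    )
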