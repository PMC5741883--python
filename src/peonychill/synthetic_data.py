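"""Seeded generators emulating a chilling-requirement study.

Three generators make every pipeline stage testable without any
external data:

* :func:`simulate_winter` — hourly winter air temperatures as the sum
  of a seasonal cosine (minimum in mid-January), a diurnal cosine
  (minimum pre-dawn), stationary AR(1) noise and a uniform warm offset
  for emulating a milder winter.
* :func:`simulate_morphology` — chill-dose-responsive morphological
  indices.  Each index follows a logistic dose-response in accumulated
  chill around a planted true requirement C*; the final-budbreak index
  is anchored so that the default adequacy criterion (95 % budbreak) is
  reached exactly at C*, making the planted requirement recoverable by
  bracket estimation.
* :func:`simulate_expression_pair` — paired-winter six-checkpoint
  expression matrices with a planted between-winter lag: "CR-congruent"
  genes carry a Gaussian activity bump centred on each winter's
  fulfillment checkpoint, "late-photoperiod" genes ramp up toward the
  last checkpoint identically in both winters, and "fluctuating" genes
  are noise.  Matching qPCR Ct tables are derived on the cycle scale.

Every generator is a pure function of its config (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chill_models import (
    ChillHourModel,
    HourlyTemperatureSeries,
    detect_start_date,
    hourly_accumulate,
)
from .cr_estimation import (
    DEFAULT_ADEQUACY_RULES,
    adequacy_labels,
    bracket_from_outcomes,
    estimate_fulfillment,
)
from .errors import ConfigError

__all__ = [
    "WinterConfig",
    "IndexSpec",
    "MorphoSimConfig",
    "ExpressionSimConfig",
    "SimulatedExpressionPair",
    "simulate_winter",
    "simulate_morphology",
    "simulate_expression_pair",
    "simulate_cr_scenario",
    "two_winter_scenario",
]


@dataclass(frozen=True)
class WinterConfig:
    """Parameters of one synthetic winter.

    Defaults describe a subtropical winter of the kind the natural
    experiments ran in: mid-winter daily means a few degrees above
    freezing, double-digit autumn temperatures, a few degrees of
    day-night swing and persistent (AR(1)) hour-to-hour weather noise.
    ``warm_offset`` shifts every reading uniformly and emulates a milder
    winter of the same shape.
    """

    start: str = "2012-11-01"
    end: str = "2013-03-15"
    seasonal_mean: float = 4.0       # °C daily-mean level at the mid-January minimum
    seasonal_amplitude: float = 12.0  # °C half-range of the annual cycle
    diurnal_amplitude: float = 4.0    # °C half-range of the day-night cycle
    ar1_rho: float = 0.8
    noise_sd: float = 1.5             # °C stationary sd of the AR(1) noise
    warm_offset: float = 0.0
    seed: int = 0
    season_label: str = ""

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ConfigError("ar1_rho must be in [0, 1)")
        span = pd.Timestamp(self.end) - pd.Timestamp(self.start)
        if span < pd.Timedelta(days=60):
            raise ConfigError("winter span must cover at least 60 days")


_SEASONAL_PERIOD_DAYS = 365.25
_SEASONAL_MIN_MONTH_DAY = (1, 15)  # coldest date of the seasonal cosine
_DIURNAL_MAX_HOUR = 15             # warmest clock hour; minimum is 03:00 (pre-dawn)


def simulate_winter(config: WinterConfig) -> HourlyTemperatureSeries:
    """Simulate one winter of hourly temperatures (deterministic per seed)."""
    idx = pd.date_range(config.start, config.end, freq="h")
    start_year = idx[0].year if idx[0].month >= 7 else idx[0].year - 1
    t_min = pd.Timestamp(start_year + 1, *_SEASONAL_MIN_MONTH_DAY)
    days_from_min = (idx - t_min) / pd.Timedelta(days=1)
    seasonal = config.seasonal_mean + config.seasonal_amplitude * (
        1.0 - np.cos(2 * np.pi * days_from_min / _SEASONAL_PERIOD_DAYS)
    )
    diurnal = config.diurnal_amplitude * np.cos(
        2 * np.pi * (idx.hour - _DIURNAL_MAX_HOUR) / 24.0
    )
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(len(idx))
    eps = np.empty(len(idx))
    if len(idx):
        eps[0] = config.noise_sd * z[0]
        innov_sd = config.noise_sd * math.sqrt(1.0 - config.ar1_rho**2)
        for i in range(1, len(idx)):
            eps[i] = config.ar1_rho * eps[i - 1] + innov_sd * z[i]
    temps = seasonal + diurnal + eps + config.warm_offset
    label = config.season_label or f"{idx[0].year}-{idx[-1].year}"
    return HourlyTemperatureSeries(pd.Series(temps, index=idx), season_label=label)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexSpec:
    """Dose-response parameters of one morphological index.

    ``anchor_value``, when set, pins the chill dose at which the index
    attains that value to exactly C* (used to align the budbreak index
    with the adequacy criterion); otherwise the logistic midpoint sits
    at C*.
    """

    baseline: float
    saturation: float
    noise_sd: float
    higher_is_better: bool = True
    anchor_value: Optional[float] = None
    floor: Optional[float] = None  # physical lower bound (e.g. counts >= 0)


def _default_indices() -> dict[str, IndexSpec]:
    return {
        "FBP": IndexSpec(20.0, 100.0, 3.0, True, anchor_value=95.0),
        "NOF": IndexSpec(0.0, 5.0, 0.4, True, floor=0.0),
        "ANS": IndexSpec(1.0, 4.0, 0.3, True, floor=0.0),
        "APH": IndexSpec(25.0, 60.0, 2.5, True),
        "DEA": IndexSpec(60.0, 12.0, 3.0, False),
    }


@dataclass(frozen=True)
class MorphoSimConfig:
    """Configuration of the morphology generator."""

    true_cr: float = 600.0          # planted chilling requirement C* (model units)
    steepness: float = 0.1          # logistic slope per chill unit
    indices: Mapping[str, IndexSpec] = field(default_factory=_default_indices)
    replicates: int = 3
    noise_scale: float = 1.0        # multiplies every index's noise_sd (0 = noiseless)
    seed: int = 0

    def __post_init__(self):
        if self.true_cr <= 0:
            raise ConfigError("true_cr must be positive")
        if self.steepness <= 0:
            raise ConfigError("steepness must be positive")

    @property
    def directions(self) -> dict[str, bool]:
        return {code: spec.higher_is_better for code, spec in self.indices.items()}


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _index_center(spec: IndexSpec, config: MorphoSimConfig) -> float:
    """Chill dose at the logistic centre, honouring the anchor value."""
    if spec.anchor_value is None:
        return config.true_cr
    frac = (spec.anchor_value - spec.baseline) / (spec.saturation - spec.baseline)
    if not 0 < frac < 1:
        raise ConfigError("anchor_value must lie strictly between baseline and saturation")
    return config.true_cr - math.log(frac / (1.0 - frac)) / config.steepness


def simulate_morphology(
    accumulations: Mapping[str, float],
    config: MorphoSimConfig,
) -> pd.DataFrame:
    """Long-format morphology table for the given per-treatment chill doses.

    Each index value is ``baseline + (saturation - baseline) *
    logistic(steepness * (chill - centre)) + noise``; lower-is-better
    indices simply have ``saturation < baseline`` so the same formula
    yields a decreasing response.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for tid in accumulations:
        chill = float(accumulations[tid])
        for code, spec in config.indices.items():
            centre = _index_center(spec, config)
            mean = spec.baseline + (spec.saturation - spec.baseline) * _logistic(
                config.steepness * (chill - centre)
            )
            noise = rng.normal(0.0, spec.noise_sd * config.noise_scale, config.replicates)
            for rep, eps in enumerate(noise, start=1):
                value = mean + eps
                if spec.floor is not None:
                    value = max(spec.floor, value)
                rows.append(
                    {
                        "treatment_id": tid,
                        "index_code": code,
                        "replicate": rep,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired-winter expression + qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the paired-winter expression generator."""

    n_genes: int = 60
    prop_cr_congruent: float = 0.3
    prop_late_photoperiod: float = 0.3
    prop_fluctuating: float = 0.4
    n_checkpoints: int = 6
    bump_width: float = 0.8      # Gaussian bump sd, in checkpoint steps
    noise_sd: float = 0.15       # additive noise on the unit-height profile
    baseline_fpkm: float = 1.0
    peak_fpkm: float = 50.0
    ct_reference_mean: float = 20.0
    ct_noise_sd: float = 0.2     # cycles
    n_biological: int = 3
    n_technical: int = 3
    seed: int = 0

    def __post_init__(self):
        total = self.prop_cr_congruent + self.prop_late_photoperiod + self.prop_fluctuating
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("class proportions must sum to 1")
        if self.n_checkpoints < 4:
            raise ConfigError("need at least 4 checkpoints")


@dataclass(frozen=True)
class SimulatedExpressionPair:
    """Output bundle of :func:`simulate_expression_pair`."""

    matrix_a: pd.DataFrame
    matrix_b: pd.DataFrame
    qpcr: pd.DataFrame
    truth: pd.Series          # gene_id -> class label
    planted_lag: int


def _class_counts(config: ExpressionSimConfig) -> dict[str, int]:
    n = config.n_genes
    n_cr = int(round(n * config.prop_cr_congruent))
    n_lp = int(round(n * config.prop_late_photoperiod))
    return {
        "cr_congruent": n_cr,
        "late_photoperiod": n_lp,
        "fluctuating": n - n_cr - n_lp,
    }


def simulate_expression_pair(
    config: ExpressionSimConfig,
    fulfillment_checkpoint_a: int,
    fulfillment_checkpoint_b: int,
) -> SimulatedExpressionPair:
    """Two FPKM matrices, a qPCR table and truth labels with a planted lag.

    CR-congruent genes peak at each winter's fulfillment checkpoint
    (0-based index), so the planted lag is ``b - a`` checkpoints.  The
    qPCR table covers winter B: reference Ct readings are drawn around
    the reference mean and target Ct values are derived as reference Ct
    minus log2(expression), with independent cycle-scale noise.
    """
    n_cp = config.n_checkpoints
    for idx in (fulfillment_checkpoint_a, fulfillment_checkpoint_b):
        if not 0 <= idx < n_cp:
            raise ConfigError("fulfillment checkpoint index outside profile")
    planted_lag = fulfillment_checkpoint_b - fulfillment_checkpoint_a
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    grid = np.arange(n_cp, dtype=float)
    cols = [f"C{i + 1}" for i in range(n_cp)]

    profiles_a, profiles_b, labels, gene_ids = [], [], [], []
    gene_no = 0
    for label, n in counts.items():
        for _ in range(n):
            gene_no += 1
            gid = f"GENE{gene_no:04d}"
            if label == "cr_congruent":
                base_a = np.exp(-((grid - fulfillment_checkpoint_a) ** 2) / (2 * config.bump_width**2))
                base_b = np.exp(-((grid - fulfillment_checkpoint_b) ** 2) / (2 * config.bump_width**2))
            elif label == "late_photoperiod":
                base_a = grid / (n_cp - 1)
                base_b = base_a.copy()
            else:
                base_a = rng.uniform(0.0, 1.0, n_cp)
                base_b = rng.uniform(0.0, 1.0, n_cp)
            prof_a = base_a + rng.normal(0.0, config.noise_sd, n_cp)
            prof_b = base_b + rng.normal(0.0, config.noise_sd, n_cp)
            profiles_a.append(np.maximum(prof_a, 0.0))
            profiles_b.append(np.maximum(prof_b, 0.0))
            labels.append(label)
            gene_ids.append(gid)

    matrix_a = pd.DataFrame(
        config.baseline_fpkm + config.peak_fpkm * np.vstack(profiles_a),
        index=gene_ids, columns=cols,
    )
    matrix_b = pd.DataFrame(
        config.baseline_fpkm + config.peak_fpkm * np.vstack(profiles_b),
        index=gene_ids, columns=cols,
    )
    matrix_a.index.name = matrix_b.index.name = "gene_id"

    qpcr_rows = []
    for cp in range(n_cp):
        for bio in range(1, config.n_biological + 1):
            ref_level = config.ct_reference_mean + rng.normal(0.0, config.ct_noise_sd)
            for tech in range(1, config.n_technical + 1):
                qpcr_rows.append(
                    {
                        "gene_id": "REFERENCE",
                        "date": cols[cp],
                        "biological": bio,
                        "technical": tech,
                        "ct": ref_level + rng.normal(0.0, config.ct_noise_sd),
                        "is_reference": True,
                    }
                )
            for gid in gene_ids:
                expr = matrix_b.at[gid, cols[cp]] / config.peak_fpkm
                target_level = ref_level - math.log2(max(expr, 1e-6))
                for tech in range(1, config.n_technical + 1):
                    qpcr_rows.append(
                        {
                            "gene_id": gid,
                            "date": cols[cp],
                            "biological": bio,
                            "technical": tech,
                            "ct": target_level + rng.normal(0.0, config.ct_noise_sd),
                            "is_reference": False,
                        }
                    )
    qpcr = pd.DataFrame(qpcr_rows)
    truth = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="class")
    return SimulatedExpressionPair(matrix_a, matrix_b, qpcr, truth, planted_lag)


# ---------------------------------------------------------------------------
# composite scenarios used by recovery checks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CRScenarioResult:
    true_cr: float
    accumulations: dict
    labels: dict
    bracket: object  # CRBracket or None when outcomes were non-monotone


def simulate_cr_scenario(
    seed: int,
    *,
    n_treatments: int = 8,
    spacing_days: int = 7,
    noise_scale: float = 1.0,
    start_threshold: float = 7.2,
) -> CRScenarioResult:
    """One full dose-ladder experiment on a simulated winter.

    Simulates a winter, lays out `n_treatments` transfer dates spaced
    `spacing_days` apart from the detected chill start, accumulates CH
    per treatment, plants a true requirement C* uniformly between 30 %
    and 70 % of the ladder maximum, simulates morphology, labels
    adequacy with the default rules and estimates the bracket.
    """
    rng = np.random.default_rng(seed)
    winter = simulate_winter(WinterConfig(seed=int(rng.integers(2**31))))
    model = ChillHourModel()
    start = detect_start_date(winter, start_threshold)
    accumulations = {}
    for k in range(n_treatments):
        end = start + pd.Timedelta(days=spacing_days * k, hours=10)
        tid = f"T{k + 1}"
        accumulations[tid] = (
            0.0 if end <= start else hourly_accumulate(winter, (start, end), model)
        )
    max_chill = max(accumulations.values())
    true_cr = float(rng.uniform(0.3, 0.7) * max_chill)
    morpho_cfg = MorphoSimConfig(
        true_cr=true_cr, noise_scale=noise_scale, seed=int(rng.integers(2**31))
    )
    morpho = simulate_morphology(accumulations, morpho_cfg)
    labels = adequacy_labels(morpho, DEFAULT_ADEQUACY_RULES)
    try:
        bracket = bracket_from_outcomes(accumulations, labels, model="CH")
    except Exception:
        bracket = None
    return CRScenarioResult(true_cr, accumulations, labels, bracket)


@dataclass(frozen=True)
class TwoWinterScenario:
    checkpoints_a: pd.Series
    checkpoints_b: pd.Series
    cr: float
    delay_days: int
    spacing_days: float
    expression: SimulatedExpressionPair


def two_winter_scenario(
    seed: int,
    *,
    warm_offset: float = 2.0,
    n_checkpoints: int = 6,
    spacing_days: int = 14,
    expression_config: ExpressionSimConfig | None = None,
) -> Optional[TwoWinterScenario]:
    """Default two-winter recovery scenario with a one-checkpoint delay.

    Winter B is winter A plus a uniform warm offset (and fresh weather
    noise), so chill accumulates more slowly.  Six sampling checkpoints
    are laid out at a fixed spacing, checkpoint chill accumulations are
    computed for both winters, and a CR value is chosen for which the
    fulfillment date falls exactly one checkpoint later in winter B —
    the construction the expression generator then mirrors with a
    planted one-checkpoint lag.  Returns None for the rare seed whose
    winters admit no such CR.
    """
    rng = np.random.default_rng(seed)
    cfg_a = WinterConfig(seed=int(rng.integers(2**31)), season_label="winter A")
    cfg_b = replace(
        cfg_a, seed=int(rng.integers(2**31)), warm_offset=warm_offset, season_label="winter B"
    )
    winter_a, winter_b = simulate_winter(cfg_a), simulate_winter(cfg_b)
    model = ChillHourModel()

    # both winters are sampled on the same calendar dates, anchored on the
    # colder winter's chill start; each winter accumulates from its own start
    start_a = detect_start_date(winter_a, 7.2)
    start_b = detect_start_date(winter_b, 7.2)
    dates = pd.DatetimeIndex(
        [start_a + pd.Timedelta(days=10 + spacing_days * k) for k in range(n_checkpoints)]
    )

    def checkpoint_series(winter, start):
        acc = [
            0.0 if d <= start else hourly_accumulate(winter, (start, d), model)
            for d in dates
        ]
        return pd.Series(acc, index=dates)

    cp_a = checkpoint_series(winter_a, start_a)
    cp_b = checkpoint_series(winter_b, start_b)

    chosen = None
    for i in range(1, n_checkpoints - 1):
        lo = max(cp_a.iloc[i - 1], cp_b.iloc[i])
        hi = min(cp_a.iloc[i], cp_b.iloc[i + 1])
        if hi > lo:
            chosen = (i, 0.5 * (lo + hi))
            break
    if chosen is None:
        return None
    i, cr = chosen
    date_a = estimate_fulfillment(cp_a, cr)
    date_b = estimate_fulfillment(cp_b, cr)
    delay_days = (date_b - date_a).days
    expr_cfg = expression_config or ExpressionSimConfig(seed=int(rng.integers(2**31)))
    pair = simulate_expression_pair(expr_cfg, i, i + 1)
    return TwoWinterScenario(
        checkpoints_a=cp_a,
        checkpoints_b=cp_b,
        cr=float(cr),
        delay_days=int(delay_days),
        spacing_days=float(spacing_days),
        expression=pair,
    )
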