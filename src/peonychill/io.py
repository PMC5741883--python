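"""Delimited-text readers/writers, run configuration and the pipeline driver.

All tabular inputs and outputs are plain delimited text (comma or tab,
autodetected or configured).  `RunConfig` validates a nested key-value
(YAML) configuration, rejecting unknown keys, and `run_pipeline` ties
the stages together into one reproducible, seeded run whose report
echoes every threshold used.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .chill_models import (
    ChillHourModel,
    ChillUnitModel,
    HourlyTemperatureSeries,
    format_chill,
)
from .congruence import CongruenceThresholds, best_lag, congruence_with_fulfillment
from .cr_estimation import DEFAULT_ADEQUACY_RULES, composite_rank, estimate_fulfillment
from .errors import ChillDataError, ConfigError
from .expression_screening import (
    AnnotationRecord,
    aggregate_qpcr_table,
    differential_screen,
    heatmap_normalize,
)
from .synthetic_data import MorphoSimConfig, simulate_cr_scenario, simulate_morphology, two_winter_scenario

logger = logging.getLogger("peonychill")

__all__ = [
    "load_temperature_table",
    "write_temperature_table",
    "load_morphology",
    "load_expression_matrix",
    "load_annotations",
    "load_qpcr",
    "write_accumulation_report",
    "RunConfig",
    "run_pipeline",
]

DEFAULT_TEMPERATURE_MAPPING = {"timestamp": "timestamp", "temp_c": "temp_c"}


def _read_delimited(path, sep: Optional[str] = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def load_temperature_table(
    path,
    mapping: Mapping[str, str] | None = None,
    season_label: str = "",
    sep: Optional[str] = None,
) -> HourlyTemperatureSeries:
    """Read an hourly temperature table into a validated series.

    The file needs a header row; `mapping` renames its columns onto the
    expected ``timestamp`` / ``temp_c`` pair, so externally formatted
    records load via a column-mapping config.  Unparseable timestamps
    are reported with their line numbers; duplicated hours are an error
    naming the hour.
    """
    mapping = dict(mapping or DEFAULT_TEMPERATURE_MAPPING)
    df = _read_delimited(path, sep=sep)
    for key in ("timestamp", "temp_c"):
        col = mapping.get(key, key)
        if col not in df.columns:
            raise ConfigError(f"column {col!r} (mapped to {key!r}) missing from {path}")
    stamps = pd.to_datetime(df[mapping["timestamp"]], errors="coerce")
    if stamps.isna().any():
        # +2: one for the header row, one for 1-based line numbering
        lines = (stamps[stamps.isna()].index + 2).tolist()
        raise ChillDataError(f"unparseable timestamp(s) at line(s) {lines[:10]} of {path}")
    dup = stamps[stamps.duplicated()]
    if not dup.empty:
        raise ChillDataError(f"duplicated hour(s) in {path}: {dup.iloc[0]}")
    temps = pd.to_numeric(df[mapping["temp_c"]], errors="coerce")
    if temps.isna().any():
        lines = (temps[temps.isna()].index + 2).tolist()
        raise ChillDataError(f"unparseable temperature(s) at line(s) {lines[:10]} of {path}")
    series = HourlyTemperatureSeries(
        pd.Series(temps.to_numpy(), index=pd.DatetimeIndex(stamps)).sort_index(),
        season_label=season_label,
    )
    if len(series.gaps):
        logger.warning("%s: %d missing hour(s) flagged", path, len(series.gaps))
    return series


def write_temperature_table(series: HourlyTemperatureSeries, path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {"timestamp": series.temps.index.strftime("%Y-%m-%dT%H:%M:%S"), "temp_c": series.temps.to_numpy()}
    )
    df.to_csv(path, sep=sep, index=False)


def load_morphology(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Long-format morphology table (treatment_id, index_code, replicate, value)."""
    df = _read_delimited(path, sep=sep)
    required = {"treatment_id", "index_code", "replicate", "value"}
    if not required.issubset(df.columns):
        raise ConfigError(f"morphology table needs columns {sorted(required)}")
    return df


def load_expression_matrix(path, sep: Optional[str] = None, gene_col: str | None = None) -> pd.DataFrame:
    """FPKM matrix: first (or named) column gene_id, remaining columns samples."""
    df = _read_delimited(path, sep=sep)
    gene_col = gene_col or df.columns[0]
    return df.set_index(gene_col)


def load_annotations(
    path,
    mapping: Mapping[str, str] | None = None,
    sep: Optional[str] = None,
) -> dict[str, AnnotationRecord]:
    """Annotation table -> gene_id-keyed records, via a column mapping."""
    default = {
        "gene_id": "gene_id",
        "homolog_locus": "homolog_locus",
        "homolog_name": "homolog_name",
        "description": "description",
    }
    mapping = {**default, **(mapping or {})}
    df = _read_delimited(path, sep=sep).fillna("")
    out = {}
    for _, row in df.iterrows():
        rec = AnnotationRecord(
            gene_id=str(row[mapping["gene_id"]]),
            homolog_locus=str(row[mapping["homolog_locus"]]),
            homolog_name=str(row[mapping["homolog_name"]]),
            description=str(row[mapping["description"]]),
        )
        if rec.gene_id in out:
            raise ConfigError(f"duplicate annotation for gene {rec.gene_id}")
        out[rec.gene_id] = rec
    return out


def load_qpcr(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Long-format qPCR table (gene_id, date, biological, technical, ct, is_reference)."""
    df = _read_delimited(path, sep=sep)
    required = {"gene_id", "date", "biological", "technical", "ct", "is_reference"}
    if not required.issubset(df.columns):
        raise ConfigError(f"qPCR table needs columns {sorted(required)}")
    return df


def write_accumulation_report(rows, path, sep: str = ",") -> None:
    """Write accumulation results with the standard report columns."""
    df = pd.DataFrame(
        rows, columns=["window_start", "window_end", "model", "total", "n_hours", "n_flagged"]
    )
    df["total"] = df["total"].map(lambda x: f"{format_chill(x):.2f}")
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------

_ALL_STAGES = ("accumulation", "cr_bracket", "fulfillment", "screening", "qpcr", "congruence")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Unknown top-level or nested threshold keys are rejected so that a
    typo cannot silently fall back to a default.
    """

    seed: int = 0
    output_dir: str = "peonychill-run"
    stages: tuple = _ALL_STAGES
    chill_model: str = "CH"
    start_rule: dict = field(default_factory=lambda: {"threshold": 7.2, "persistence_days": 3})
    adequacy_rules: dict = field(default_factory=lambda: dict(DEFAULT_ADEQUACY_RULES))
    screening: dict = field(
        default_factory=lambda: {"fold_threshold": 4.0, "min_peak": 1.0, "pseudocount": 0.1}
    )
    congruence: dict = field(
        default_factory=lambda: {"r_high": 0.8, "r_mid": 0.5, "gain": 0.2, "max_lag": 2}
    )

    _NESTED_KEYS = {
        "start_rule": {"threshold", "persistence_days"},
        "screening": {"fold_threshold", "min_peak", "pseudocount"},
        "congruence": {"r_high", "r_mid", "gain", "max_lag"},
    }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {"seed", "output_dir", "stages", "chill_model", "start_rule",
                 "adequacy_rules", "screening", "congruence"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls()
        for key, value in raw.items():
            if key in cls._NESTED_KEYS:
                extra = set(value) - cls._NESTED_KEYS[key]
                if extra:
                    raise ConfigError(f"unknown {key} key(s): {sorted(extra)}")
                merged = dict(getattr(cfg, key))
                merged.update(value)
                value = merged
            if key == "stages":
                bad = set(value) - set(_ALL_STAGES)
                if bad:
                    raise ConfigError(f"unknown stage(s): {sorted(bad)}")
                value = tuple(value)
            if key == "adequacy_rules":
                value = {ix: (op, float(thr)) for ix, (op, thr) in value.items()}
            setattr(cfg, key, value)
        if cfg.chill_model not in ("CH", "CU"):
            raise ConfigError("chill_model must be 'CH' or 'CU'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def model(self):
        return ChillHourModel() if self.chill_model == "CH" else ChillUnitModel()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages on the default synthetic scenario.

    Runs the seeded two-winter scenario (chill accumulation, CR bracket
    from a simulated dose ladder, fulfillment comparison, expression
    screening, qPCR aggregation, lag congruence) and writes the result
    tables, a JSON report and a log of versions, seed and thresholds to
    the output directory.  Any stage failure aborts with a stage-tagged
    message.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {"peonychill": __version__, "python": platform.python_version()},
        "seed": config.seed,
        "thresholds": {
            "chill_model": config.chill_model,
            "start_rule": config.start_rule,
            "adequacy_rules": {k: list(v) for k, v in config.adequacy_rules.items()},
            "screening": config.screening,
            "congruence": config.congruence,
        },
        "stages": {},
    }

    def _stage(name):
        return name in config.stages

    scenario = None
    if _stage("accumulation") or _stage("fulfillment") or _stage("congruence") or _stage(
        "screening"
    ) or _stage("qpcr"):
        # the rare seed admits no one-checkpoint CR; step deterministically to
        # the next seed that does, and record which one was used
        for offset in range(16):
            scenario = two_winter_scenario(config.seed + offset)
            if scenario is not None:
                report["scenario_seed"] = config.seed + offset
                break
        if scenario is None:  # pragma: no cover - 16 consecutive misses
            raise RuntimeError("[accumulation] no workable scenario seed found")

    try:
        if _stage("accumulation"):
            cps = pd.DataFrame(
                {
                    "winter_a": scenario.checkpoints_a.to_numpy(),
                    "winter_b": scenario.checkpoints_b.to_numpy(),
                },
                index=scenario.checkpoints_a.index.strftime("%Y-%m-%d %H:%M"),
            )
            cps.to_csv(out_dir / "checkpoint_accumulations.csv")
            report["stages"]["accumulation"] = {
                "checkpoints": {
                    "winter_a": [format_chill(v) for v in scenario.checkpoints_a],
                    "winter_b": [format_chill(v) for v in scenario.checkpoints_b],
                }
            }
    except ConfigError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"[accumulation] {exc}") from exc

    if _stage("cr_bracket"):
        try:
            cr_scn = simulate_cr_scenario(config.seed)
            morpho = simulate_morphology(
                cr_scn.accumulations, MorphoSimConfig(true_cr=cr_scn.true_cr, seed=config.seed)
            )
            ranking = composite_rank(
                morpho,
                MorphoSimConfig().directions,
                accumulations=cr_scn.accumulations,
            )
            ranking.to_csv(out_dir / "composite_ranking.csv")
            report["stages"]["cr_bracket"] = {
                "bracket": str(cr_scn.bracket) if cr_scn.bracket else None,
                "labels": cr_scn.labels,
                "optimal_treatment": str(ranking.index[0]),
            }
        except Exception as exc:
            raise RuntimeError(f"[cr_bracket] {exc}") from exc

    if _stage("fulfillment"):
        try:
            days = scenario.delay_days
            report["stages"]["fulfillment"] = {
                "cr": format_chill(scenario.cr),
                "date_a": str(estimate_fulfillment(scenario.checkpoints_a, scenario.cr)),
                "date_b": str(estimate_fulfillment(scenario.checkpoints_b, scenario.cr)),
                "delay_days": days,
                "delay_weeks": int(round(days / 7)),
            }
        except Exception as exc:
            raise RuntimeError(f"[fulfillment] {exc}") from exc

    screened = None
    if _stage("screening"):
        try:
            matrix_b = scenario.expression.matrix_b
            screened = differential_screen(matrix_b, **config.screening)
            normalized = heatmap_normalize(matrix_b.loc[screened])
            normalized.to_csv(out_dir / "heatmap_matrix.csv")
            report["stages"]["screening"] = {
                "n_input_genes": int(len(matrix_b)),
                "n_screened": int(len(screened)),
            }
        except Exception as exc:
            raise RuntimeError(f"[screening] {exc}") from exc

    if _stage("qpcr"):
        try:
            qpcr = scenario.expression.qpcr
            subset_genes = list(scenario.expression.truth.index[:12]) + ["REFERENCE"]
            agg = aggregate_qpcr_table(qpcr[qpcr["gene_id"].isin(subset_genes)])
            agg.to_csv(out_dir / "qpcr_expression.csv", index=False)
            report["stages"]["qpcr"] = {"n_rows": int(len(agg))}
        except Exception as exc:
            raise RuntimeError(f"[qpcr] {exc}") from exc

    if _stage("congruence"):
        try:
            thresholds = CongruenceThresholds(
                r_high=config.congruence["r_high"],
                r_mid=config.congruence["r_mid"],
                gain=config.congruence["gain"],
            )
            za = heatmap_normalize(scenario.expression.matrix_a)
            zb = heatmap_normalize(scenario.expression.matrix_b)
            rows = []
            for gid in za.index:
                result = best_lag(
                    za.loc[gid].to_numpy(),
                    zb.loc[gid].to_numpy(),
                    max_lag=config.congruence["max_lag"],
                )
                rep = congruence_with_fulfillment(
                    result, scenario.delay_days, scenario.spacing_days, thresholds
                )
                rows.append(
                    {
                        "gene_id": gid,
                        "best_lag": result.best_lag,
                        "r_zero": result.r_zero,
                        "r_best": result.r_best,
                        "type": rep.congruence_type,
                        "cr_congruent": rep.congruent,
                    }
                )
            cong = pd.DataFrame(rows)
            cong.to_csv(out_dir / "congruence.csv", index=False)
            report["stages"]["congruence"] = {
                "n_genes": int(len(cong)),
                "n_cr_congruent": int(cong["cr_congruent"].fillna(False).sum()),
            }
        except Exception as exc:
            raise RuntimeError(f"[congruence] {exc}") from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"peonychill {__version__} (python {platform.python_version()})\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"thresholds: {json.dumps(report['thresholds'], default=str)}\n")
        fh.write(f"stages run: {', '.join(s for s in config.stages)}\n")
    return report
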