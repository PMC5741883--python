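"""Packaged reference tables from the chilling-requirement study.

Small delimited-text fixtures shipped with the package: the treatment
schedules of the two CR experiments, the published per-treatment chill
accumulations, the six-checkpoint chill key points of the two compared
winters, the per-homolog counts of the screened candidate genes, and
the direction registry of the morphological index codes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cr_estimation import Treatment

__all__ = [
    "load_treatments",
    "load_reported_accumulations",
    "load_checkpoint_series",
    "load_homolog_counts",
    "load_index_directions",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("peonychill.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_treatments(experiment: str | None = None) -> list[Treatment]:
    """Treatment schedules (natural 2012–13 ladder, artificial 2013–14 ladder).

    `experiment` filters on ``natural_2012`` / ``artificial_2013``.
    """
    df = _read("treatments.csv")
    if experiment is not None:
        df = df[df["experiment"] == experiment]
    out = []
    for _, row in df.iterrows():
        out.append(
            Treatment(
                id=row["treatment_id"],
                mode=row["mode"],
                chill_end=pd.Timestamp(row["chill_end"]),
                chill_start=pd.Timestamp(row["chill_start"])
                if pd.notna(row["chill_start"])
                else None,
                storage_temp=float(row["storage_temp"])
                if pd.notna(row["storage_temp"])
                else None,
            )
        )
    return out


def load_reported_accumulations() -> pd.DataFrame:
    """Published per-treatment CH and CU accumulations (both experiments)."""
    return _read("reported_accumulations.csv", parse_dates=["transfer_date"])


def load_checkpoint_series(winter: str) -> pd.Series:
    """Published key-time-point CH accumulations of one winter.

    `winter` is ``"2012-2013"`` or ``"2015-2016"``.  Returns cumulative
    CH indexed by sampling date.  The per-interval increments are in the
    underlying table (``load_checkpoint_table``).
    """
    df = load_checkpoint_table()
    sel = df[df["winter"] == winter]
    if sel.empty:
        raise KeyError(f"unknown winter {winter!r}")
    return pd.Series(
        sel["cumulative_ch"].to_numpy(dtype=float),
        index=pd.DatetimeIndex(sel["date"]),
        name=winter,
    )


def load_checkpoint_table() -> pd.DataFrame:
    """Full checkpoint table: winter, date, per-interval and cumulative CH."""
    return _read("checkpoints.csv", parse_dates=["date"])


def load_homolog_counts() -> pd.DataFrame:
    """Per-homolog counts of the screened temperature/photoperiod genes."""
    return _read("homolog_counts.csv")


def load_index_directions() -> dict[str, bool]:
    """Morphological index registry: code -> higher-is-better flag."""
    df = _read("index_directions.csv")
    return dict(zip(df["index_code"], df["higher_is_better"].astype(bool)))
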