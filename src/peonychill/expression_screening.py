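"""Candidate-gene screening from an annotated FPKM matrix, plus qPCR maths.

The screening stage consumes a gene × checkpoint FPKM matrix (six dated
bud samples across one winter) together with per-gene homology
annotations, and retains genes that (a) vary substantially across the
winter (fold-change filter with a pseudocount) and (b) are annotated
with temperature- or photoperiod-related vocabulary.  Retained genes
are grouped by their closest *Arabidopsis* homolog for bookkeeping, and
their profiles are row-standardized (z-score, clipped) for heatmap
display.

qPCR quantification uses the 2^-ΔCt method against an in-sample
reference gene: technical triplicates are averaged on the Ct (cycle)
scale within each biological replicate, expression is computed per
biological replicate, and the mean ± sd across biological replicates is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "AnnotationRecord",
    "KeywordRuleSet",
    "QPCRRecord",
    "QPCRResult",
    "validate_expression_matrix",
    "differential_screen",
    "keyword_classify",
    "summarize_by_homolog",
    "heatmap_normalize",
    "relative_expression",
    "aggregate_qpcr",
    "aggregate_qpcr_table",
]

#: Phrases whose presence in an annotation marks a temperature-responsive gene.
TEMPERATURE_KEYWORDS = (
    "temperature response",
    "cold response",
    "cold regulated",
    "cold-regulated",
    "cold acclimation",
    "deacclimation",
    "cold-inducible",
    "low temperature",
    "heat shock",
    "osmotin",
    "responsive to dehydration",
    "responsive to aba",
)

#: Phrases marking a photoperiod / light / circadian associated gene.
PHOTOPERIOD_KEYWORDS = (
    "light harvesting",
    "light mediated",
    "light chain",
    "photosystem",
    "photosynthesis",
    "phototropin",
    "phytochrome",
    "circadian rhythm",
    "circadian regulation",
    "late elongated hypocotyl",
    "photoperiod",
)


@dataclass(frozen=True)
class AnnotationRecord:
    """Homology annotation of one assembled unigene."""

    gene_id: str
    homolog_locus: str = ""
    homolog_name: str = ""
    description: str = ""

    @property
    def incomplete(self) -> bool:
        return not (self.homolog_locus and self.homolog_name and self.description)


@dataclass(frozen=True)
class KeywordRuleSet:
    """Case-insensitive substring rules for the two candidate classes."""

    temperature_keywords: tuple = TEMPERATURE_KEYWORDS
    photoperiod_keywords: tuple = PHOTOPERIOD_KEYWORDS

    def __post_init__(self):
        t = tuple(k.lower() for k in self.temperature_keywords)
        p = tuple(k.lower() for k in self.photoperiod_keywords)
        if not t or not p:
            raise ConfigError("keyword lists must be non-empty")
        dup = set(t) & set(p)
        if dup:
            raise ConfigError(f"phrase(s) in both keyword lists: {sorted(dup)}")
        object.__setattr__(self, "temperature_keywords", t)
        object.__setattr__(self, "photoperiod_keywords", p)


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an FPKM matrix: unique gene ids, finite non-negative values."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ConfigError(f"duplicate gene id(s): {dups[:5]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ConfigError("non-finite FPKM value")
    if (values < 0).any():
        raise ConfigError("negative FPKM value")
    return matrix


def differential_screen(
    matrix: pd.DataFrame,
    fold_threshold: float = 4.0,
    min_peak: float = 1.0,
    pseudocount: float = 0.1,
) -> pd.Index:
    """Genes whose profiles vary substantially across checkpoints.

    A gene is retained iff
    ``(max + pseudocount) / (min + pseudocount) >= fold_threshold``
    and ``max >= min_peak``.  The pseudocount guards against division
    by zero for silent genes and damps ratios of near-zero profiles.
    """
    if fold_threshold <= 1:
        raise ConfigError("fold_threshold must exceed 1")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    validate_expression_matrix(matrix)
    mx = matrix.max(axis=1)
    mn = matrix.min(axis=1)
    keep = ((mx + pseudocount) / (mn + pseudocount) >= fold_threshold) & (mx >= min_peak)
    return matrix.index[keep]


def keyword_classify(
    record: AnnotationRecord,
    rules: KeywordRuleSet | None = None,
) -> tuple[str, tuple, bool]:
    """Classify one annotation as temperature / photoperiod / none.

    Matching is case-insensitive substring search over the description
    plus homolog name.  When both classes match, temperature wins and
    the returned both-flag is set.

    Returns ``(category, matched_phrases, both_flag)``.
    """
    rules = rules or KeywordRuleSet()
    text = f"{record.description} {record.homolog_name}".lower()
    t_hits = tuple(k for k in rules.temperature_keywords if k in text)
    p_hits = tuple(k for k in rules.photoperiod_keywords if k in text)
    if t_hits:
        return "temperature", t_hits + p_hits, bool(p_hits)
    if p_hits:
        return "photoperiod", p_hits, False
    return "none", (), False


def summarize_by_homolog(
    gene_ids: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    missing_label: str = "No Arabidopsis gene name",
) -> tuple[pd.DataFrame, int]:
    """Count screened genes per homolog name.

    Every gene id must have an annotation record (KeyError otherwise);
    records without a homolog name are pooled under `missing_label`.
    Returns ``(table, total)`` where the table has columns
    ``homolog_name`` and ``count`` and total equals the gene-set size.
    """
    gene_ids = list(gene_ids)
    names = []
    for gid in gene_ids:
        if gid not in annotations:
            raise KeyError(f"unannotated gene id: {gid}")
        name = annotations[gid].homolog_name.strip()
        names.append(name if name else missing_label)
    counts = pd.Series(names, dtype=object).value_counts()
    table = counts.rename_axis("homolog_name").reset_index(name="count")
    return table, int(table["count"].sum())


def heatmap_normalize(matrix: pd.DataFrame, clip: float = 3.0) -> pd.DataFrame:
    """Row-standardize FPKM profiles for heatmap display.

    Each gene's profile is centred on its mean and divided by its
    population (n-denominator) standard deviation, then clipped to
    ``[-clip, +clip]``.  Constant genes map to all zeros.
    """
    if clip <= 0:
        raise ConfigError("clip must be positive")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(np.clip(z, -clip, clip), index=matrix.index, columns=matrix.columns)


def relative_expression(target_ct: float, reference_ct: float) -> float:
    """Fold expression of target vs reference gene: ``2 ** -(Ct_t - Ct_r)``."""
    delta = np.asarray(target_ct, dtype=float) - np.asarray(reference_ct, dtype=float)
    if not np.isfinite(delta).all():
        raise ValueError("Ct values must be finite")
    out = 2.0 ** (-delta)
    return out if out.ndim else float(out)


@dataclass
class QPCRRecord:
    """Raw Ct readings for one gene at one checkpoint.

    ``target_ct`` and ``reference_ct`` are (biological × technical)
    arrays of cycle thresholds — the study design is 3 × 3 — measured on
    the same cDNA samples; the reference gene is an internal control
    whose transcription is stable across the winter.  NaN marks a
    missing reading.
    """

    gene_id: str
    checkpoint: str
    target_ct: np.ndarray
    reference_ct: np.ndarray
    flag_range: float = 0.5  # technical triplicate spread worth flagging (cycles)

    def __post_init__(self):
        self.target_ct = np.atleast_2d(np.asarray(self.target_ct, dtype=float))
        self.reference_ct = np.atleast_2d(np.asarray(self.reference_ct, dtype=float))
        for arr in (self.target_ct, self.reference_ct):
            vals = arr[np.isfinite(arr)]
            if ((vals <= 0) | (vals >= 45)).any():
                raise ValueError("Ct values must lie in (0, 45) cycles")


@dataclass(frozen=True)
class QPCRResult:
    """Aggregated relative expression for one gene at one checkpoint."""

    gene_id: str
    checkpoint: str
    mean_expression: float
    sd_expression: float
    per_replicate: tuple
    flagged_replicates: tuple  # biological replicates with technical range > threshold


def aggregate_qpcr(record: QPCRRecord) -> QPCRResult:
    """2^-ΔCt aggregation of one record.

    Technical replicates are averaged on the Ct scale within each
    biological replicate (separately for target and reference), each
    biological replicate yields one relative expression against its own
    reference mean, and the mean and standard deviation (ddof=1, 0 for a
    single replicate) across biological replicates are reported.
    Biological replicates whose technical spread exceeds the flag
    threshold are flagged but not excluded.
    """
    rels, flagged = [], []
    n_bio = record.target_ct.shape[0]
    for b in range(n_bio):
        t_row = record.target_ct[b][np.isfinite(record.target_ct[b])]
        r_row = record.reference_ct[b][np.isfinite(record.reference_ct[b])]
        if len(t_row) == 0 or len(r_row) == 0:
            continue
        if (len(t_row) > 1 and np.ptp(t_row) > record.flag_range) or (
            len(r_row) > 1 and np.ptp(r_row) > record.flag_range
        ):
            flagged.append(b)
        rels.append(relative_expression(t_row.mean(), r_row.mean()))
    if not rels:
        raise ValueError(f"{record.gene_id}/{record.checkpoint}: all readings missing")
    rels = np.asarray(rels)
    sd = float(rels.std(ddof=1)) if len(rels) > 1 else 0.0
    return QPCRResult(
        gene_id=record.gene_id,
        checkpoint=record.checkpoint,
        mean_expression=float(rels.mean()),
        sd_expression=sd,
        per_replicate=tuple(float(r) for r in rels),
        flagged_replicates=tuple(flagged),
    )


def aggregate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format qPCR table to mean ± sd per gene/checkpoint.

    Expected columns: ``gene_id, date, biological, technical, ct,
    is_reference``.  Reference rows are matched to targets of the same
    date and biological replicate.
    """
    required = {"gene_id", "date", "biological", "technical", "ct", "is_reference"}
    if not required.issubset(table.columns):
        raise ConfigError(f"qPCR table needs columns {sorted(required)}")
    is_ref = table["is_reference"].astype(bool)
    refs = table[is_ref]
    targets = table[~is_ref]
    out = []
    for (gid, date), grp in targets.groupby(["gene_id", "date"], sort=False):
        ref_grp = refs[refs["date"] == date]
        if ref_grp.empty:
            raise ConfigError(f"no reference readings for checkpoint {date}")
        t_ct = grp.pivot_table(index="biological", columns="technical", values="ct")
        r_ct = ref_grp.pivot_table(index="biological", columns="technical", values="ct")
        r_ct = r_ct.reindex(t_ct.index)
        rec = QPCRRecord(str(gid), str(date), t_ct.to_numpy(), r_ct.to_numpy())
        res = aggregate_qpcr(rec)
        out.append(
            {
                "gene_id": gid,
                "date": date,
                "mean_expression": res.mean_expression,
                "sd_expression": res.sd_expression,
                "n_biological": len(res.per_replicate),
                "n_flagged": len(res.flagged_replicates),
            }
        )
    return pd.DataFrame(out)
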