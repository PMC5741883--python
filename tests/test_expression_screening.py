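"""Differential screening, keyword classification, heatmap scaling and qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peonychill import (
    AnnotationRecord,
    KeywordRuleSet,
    QPCRRecord,
    aggregate_qpcr,
    aggregate_qpcr_table,
    differential_screen,
    heatmap_normalize,
    keyword_classify,
    relative_expression,
    summarize_by_homolog,
)
from peonychill.datasets import load_homolog_counts
from peonychill.errors import ConfigError


def _matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"C{i}" for i in range(1, 7)])


class TestDifferentialScreen:
    def test_flat_profile_excluded_single_peak_included(self):
        m = _matrix({"flat": [1, 1, 1, 1, 1, 1], "peak": [1, 1, 1, 10, 1, 1]})
        kept = differential_screen(m)
        assert list(kept) == ["peak"]  # (10.1 / 1.1) = 9.18 >= 4

    def test_all_zero_profile_handled_by_pseudocount(self):
        m = _matrix({"silent": [0, 0, 0, 0, 0, 0]})
        assert len(differential_screen(m)) == 0

    def test_min_peak_filters_low_abundance(self):
        m = _matrix({"dim": [0.01, 0.01, 0.01, 0.5, 0.01, 0.01]})
        assert len(differential_screen(m, min_peak=1.0)) == 0
        assert list(differential_screen(m, min_peak=0.1)) == ["dim"]

    def test_column_permutation_invariance(self):
        m = _matrix({"a": [1, 2, 9, 1, 1, 1], "b": [3, 3, 3, 3, 3, 4]})
        shuffled = m[["C4", "C2", "C6", "C1", "C3", "C5"]]
        assert list(differential_screen(m)) == list(differential_screen(shuffled))

    @given(st.floats(min_value=0.5, max_value=20.0))
    def test_scale_covariance(self, scale):
        m = _matrix({"a": [1, 2, 9, 1, 1, 1], "b": [3, 3, 3, 3, 3, 4], "c": [0, 0, 5, 0, 0, 0]})
        base = set(differential_screen(m, pseudocount=0.1, min_peak=1.0))
        scaled = set(
            differential_screen(m * scale, pseudocount=0.1 * scale, min_peak=1.0 * scale)
        )
        assert base == scaled

    def test_negative_values_rejected(self):
        with pytest.raises(ConfigError):
            differential_screen(_matrix({"a": [1, -1, 1, 1, 1, 1]}))

    def test_duplicate_gene_ids_rejected(self):
        m = pd.concat([_matrix({"a": [1] * 6}), _matrix({"a": [2] * 6})])
        with pytest.raises(ConfigError, match="duplicate"):
            differential_screen(m)


class TestKeywordClassification:
    @pytest.mark.parametrize(
        "description, name, expected",
        [
            ("COLD-REGULATED 47", "COR47", "temperature"),
            ("PHOTOSYSTEM I LIGHT HARVESTING COMPLEX GENE 6", "LHCA6", "photoperiod"),
            ("Ribosomal protein L23/L15e family protein", "RPL15A", "none"),
            ("HEAT SHOCK PROTEIN 18.2", "HSP18.2", "temperature"),
            ("circadian regulation pseudo-response regulator", "APRR3", "photoperiod"),
        ],
    )
    def test_classification_of_annotations(self, description, name, expected):
        rec = AnnotationRecord("g", "AT0G00000", name, description)
        category, matched, _ = keyword_classify(rec)
        assert category == expected
        assert (category == "none") == (len(matched) == 0)

    def test_dual_match_prefers_temperature_with_flag(self):
        rec = AnnotationRecord("g", "", "", "cold response of the photosystem apparatus")
        category, matched, both = keyword_classify(rec)
        assert category == "temperature" and both
        assert "cold response" in matched and "photosystem" in matched

    def test_matching_is_case_insensitive(self):
        rec = AnnotationRecord("g", "", "", "Heat Shock cognate protein")
        assert keyword_classify(rec)[0] == "temperature"

    def test_overlapping_rule_lists_rejected(self):
        with pytest.raises(ConfigError):
            KeywordRuleSet(("cold",), ("COLD",))


class TestHomologSummary:
    def test_counts_and_total(self):
        annotations = {
            "g1": AnnotationRecord("g1", "AT2G45660", "SOC1", ""),
            "g2": AnnotationRecord("g2", "AT2G45660", "SOC1", ""),
            "g3": AnnotationRecord("g3", "AT1G20440", "COR47", ""),
            "g4": AnnotationRecord("g4", "", "", "unknown"),
        }
        table, total = summarize_by_homolog(annotations.keys(), annotations)
        counts = dict(zip(table.homolog_name, table["count"]))
        assert counts == {"SOC1": 2, "COR47": 1, "No Arabidopsis gene name": 1}
        assert total == 4

    def test_total_equals_gene_set_size_and_empty_set(self):
        annotations = {"g1": AnnotationRecord("g1", "", "X", "")}
        table, total = summarize_by_homolog([], annotations)
        assert total == 0 and len(table) == 0

    def test_unannotated_gene_is_lookup_error(self):
        with pytest.raises(KeyError):
            summarize_by_homolog(["ghost"], {})

    def test_published_homolog_table_books_sixty_six(self):
        hc = load_homolog_counts()
        assert int(hc["count"].sum()) == 66
        heat_shock = hc.loc[hc["abbreviation"] == "HSP/HSC/HSF", "count"].item()
        assert int(heat_shock) == 17


class TestHeatmapNormalize:
    def test_two_point_row_standardizes_to_unit_deviation(self):
        m = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["a", "b"])
        assert heatmap_normalize(m).loc["g"].tolist() == [-1.0, 1.0]

    def test_constant_row_maps_to_zero(self):
        m = pd.DataFrame([[2.0] * 6], index=["g"])
        assert (heatmap_normalize(m).loc["g"] == 0).all()

    def test_outlier_clipped_to_limit(self):
        row = [0.0] * 30 + [1000.0]
        m = pd.DataFrame([row], index=["g"])
        z = heatmap_normalize(m, clip=3.0)
        assert z.loc["g"].max() == 3.0

    # FPKM-scale magnitudes (exact zeros allowed); values within a few orders
    # of magnitude of double-precision underflow are out of scope
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1e4)),
            min_size=4,
            max_size=12,
        )
    )
    def test_rows_have_zero_mean_unit_population_sd_pre_clip(self, values):
        m = pd.DataFrame([values], index=["g"])
        if np.ptp(values) == 0:
            assert (heatmap_normalize(m).loc["g"] == 0).all()
            return
        z = heatmap_normalize(m, clip=1e9).loc["g"].to_numpy()  # huge clip: no truncation
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-9)


class TestQPCR:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.0, 1.0), (1.0, 0.5), (3.321928, 0.1), (-1.0, 2.0)],
    )
    def test_relative_expression_halves_per_cycle(self, delta, expected):
        assert relative_expression(20.0 + delta, 20.0) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(min_value=5, max_value=40), st.floats(min_value=0.1, max_value=5))
    def test_strictly_decreasing_in_target_ct(self, ct, dt):
        assert relative_expression(ct + dt, 20.0) < relative_expression(ct, 20.0)

    def test_identical_readings_give_unit_expression(self):
        rec = QPCRRecord("g", "C1", np.full((3, 3), 25.0), np.full((3, 3), 25.0))
        res = aggregate_qpcr(rec)
        assert res.mean_expression == 1.0 and res.sd_expression == 0.0

    def test_biological_replicates_averaged_on_expression_scale(self):
        target = np.array([[20.0] * 3, [21.0] * 3, [22.0] * 3])
        reference = np.full((3, 3), 20.0)
        res = aggregate_qpcr(QPCRRecord("g", "C1", target, reference))
        assert res.per_replicate == (1.0, 0.5, 0.25)
        assert res.mean_expression == pytest.approx(np.mean([1.0, 0.5, 0.25]))
        assert res.sd_expression == pytest.approx(np.std([1.0, 0.5, 0.25], ddof=1))

    def test_wide_technical_spread_flagged_not_dropped(self):
        target = np.array([[20.0, 20.8, 20.0], [21.0] * 3, [21.0] * 3])
        res = aggregate_qpcr(QPCRRecord("g", "C1", target, np.full((3, 3), 20.0)))
        assert res.flagged_replicates == (0,)
        assert len(res.per_replicate) == 3

    def test_all_missing_is_input_error(self):
        nan = np.full((3, 3), np.nan)
        with pytest.raises(ValueError, match="missing"):
            aggregate_qpcr(QPCRRecord("g", "C1", nan, nan))

    def test_ct_outside_plausible_cycles_rejected(self):
        with pytest.raises(ValueError):
            QPCRRecord("g", "C1", np.full((1, 3), 50.0), np.full((1, 3), 20.0))

    def test_long_table_aggregation_matches_record_route(self):
        rows = []
        for bio in (1, 2, 3):
            for tech in (1, 2, 3):
                rows.append(("target", "d1", bio, tech, 20.0 + bio, False))
                rows.append(("ref", "d1", bio, tech, 20.0, True))
        table = pd.DataFrame(
            rows, columns=["gene_id", "date", "biological", "technical", "ct", "is_reference"]
        )
        agg = aggregate_qpcr_table(table)
        target = np.array([[21.0] * 3, [22.0] * 3, [23.0] * 3])
        direct = aggregate_qpcr(QPCRRecord("target", "d1", target, np.full((3, 3), 20.0)))
        assert agg.loc[0, "mean_expression"] == pytest.approx(direct.mean_expression)
        assert agg.loc[0, "sd_expression"] == pytest.approx(direct.sd_expression)
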