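"""CR brackets, adequacy rules, composite ranking and reverse use."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peonychill import (
    ChillHourModel,
    ChillUnitModel,
    CRBracket,
    Treatment,
    adequacy_labels,
    bracket_from_outcomes,
    composite_rank,
    estimate_fulfillment,
    format_chill,
    fulfillment_delay,
    intersect_brackets,
    treatment_accumulation,
)
from peonychill.datasets import load_checkpoint_series, load_treatments
from peonychill.errors import (
    ConfigError,
    EstimationError,
    UndefinedDelayError,
    UnitMismatchError,
)
from peonychill.synthetic_data import simulate_winter, WinterConfig
from peonychill.chill_models import hourly_accumulate, detect_start_date


class TestTreatmentAccumulation:
    def test_storage_ladder_reproduces_published_doses(self):
        treatments = load_treatments("artificial_2013")
        cu, ch = ChillUnitModel(), ChillHourModel()
        got_cu = [format_chill(treatment_accumulation(t, None, cu)) for t in treatments]
        got_ch = [treatment_accumulation(t, None, ch) for t in treatments]
        assert got_cu == [0.0, 147.67, 295.34, 443.02, 590.69, 738.36]
        assert got_ch == [0.0, 168.0, 336.0, 504.0, 672.0, 840.0]

    def test_natural_transfer_before_start_is_blank_control(self, make_constant_series):
        series = make_constant_series(5.0, 24 * 20, start="2012-12-01 00:00")
        early = Treatment("blank", "natural", chill_end="2012-11-26 10:00")
        assert (
            treatment_accumulation(early, series, ChillHourModel(), start="2012-12-08")
            == 0.0
        )

    def test_natural_needs_series(self):
        t = Treatment("T", "natural", chill_end="2012-12-10 10:00")
        with pytest.raises(EstimationError):
            treatment_accumulation(t, None, ChillHourModel(), start="2012-12-08")

    def test_natural_accumulates_from_supplied_start(self, make_constant_series):
        series = make_constant_series(5.0, 24 * 20, start="2012-12-01 00:00")
        t = Treatment("T", "natural", chill_end="2012-12-10 10:00")
        total = treatment_accumulation(t, series, ChillHourModel(), start="2012-12-08")
        assert total == 58.0  # 2 days + 10 h of in-band hours


class TestAdequacy:
    def test_default_rules_split_dose_ladder(self, small_morpho):
        labels = adequacy_labels(small_morpho)
        assert labels == {"T1": "inadequate", "T2": "adequate", "T3": "adequate"}

    def test_no_flower_treatment_inadequate_despite_high_budbreak(self, small_morpho):
        morpho = small_morpho.copy()
        morpho.loc[
            (morpho.treatment_id == "T2") & (morpho.index_code == "NOF"), "value"
        ] = 0.0
        assert adequacy_labels(morpho)["T2"] == "inadequate"

    def test_rule_referencing_absent_index_is_config_error(self, small_morpho):
        with pytest.raises(ConfigError):
            adequacy_labels(small_morpho, {"BBP": (">=", 50.0)})

    def test_empty_table_is_config_error(self):
        with pytest.raises(ConfigError):
            adequacy_labels(pd.DataFrame())


class TestBrackets:
    def test_bracket_from_outcomes_boundaries(self):
        acc = {"T1": 0.0, "T2": 483.0, "T3": 738.0, "T4": 892.0}
        labels = {"T1": "inadequate", "T2": "inadequate", "T3": "adequate", "T4": "adequate"}
        bracket = bracket_from_outcomes(acc, labels, model="CH")
        assert (bracket.lower, bracket.upper) == (483.0, 738.0)
        assert bracket.lower_open and not bracket.upper_open

    def test_all_adequate_gives_zero_closed_lower(self):
        bracket = bracket_from_outcomes({"a": 100.0, "b": 200.0}, {"a": "adequate", "b": "adequate"})
        assert (bracket.lower, bracket.lower_open) == (0.0, False)
        assert bracket.upper == 100.0

    def test_no_adequate_treatment_is_estimation_error(self):
        with pytest.raises(EstimationError, match="exceeds maximum"):
            bracket_from_outcomes({"a": 100.0}, {"a": "inadequate"})

    def test_published_ch_intervals_intersect(self):
        natural = CRBracket(483.0, 738.0, "CH")
        artificial = CRBracket(504.0, 672.0, "CH")
        both = intersect_brackets(natural, artificial)
        assert (both.lower, both.upper) == (504.0, 672.0)

    def test_published_cu_intervals_disjoint(self):
        natural = CRBracket(615.27, 856.08, "CU", lower_open=False)
        artificial = CRBracket(443.02, 590.69, "CU", lower_open=False)
        assert intersect_brackets(natural, artificial) is None

    def test_intersection_algebra(self):
        a = CRBracket(100.0, 500.0, "CH")
        b = CRBracket(200.0, 400.0, "CH")
        assert intersect_brackets(a, a) == a
        assert intersect_brackets(a, b) == intersect_brackets(b, a)
        assert intersect_brackets(a, b) == b  # nested -> inner bracket

    def test_model_mismatch_is_unit_error(self):
        with pytest.raises(UnitMismatchError):
            intersect_brackets(CRBracket(0, 1, "CH"), CRBracket(0, 1, "CU"))

    @given(
        st.lists(
            st.tuples(st.floats(0, 1000), st.booleans()), min_size=1, max_size=12
        ).filter(lambda xs: any(adq for _, adq in xs))
    )
    def test_bracket_bounds_ordered_or_error(self, outcomes):
        acc = {f"T{i}": chill for i, (chill, _) in enumerate(outcomes)}
        labels = {
            f"T{i}": "adequate" if adq else "inadequate"
            for i, (_, adq) in enumerate(outcomes)
        }
        try:
            bracket = bracket_from_outcomes(acc, labels)
        except EstimationError:
            return  # non-monotone outcomes are a declared error, not a bad bracket
        assert bracket.lower <= bracket.upper


class TestCompositeRank:
    def test_single_index_ranks_by_value(self, small_morpho):
        fbp_only = small_morpho[small_morpho.index_code == "FBP"]
        ranking = composite_rank(fbp_only, {"FBP": True})
        assert list(ranking.index) == ["T3", "T2", "T1"]

    def test_identical_rows_tie_break_toward_lower_chill(self, small_morpho):
        flat = small_morpho.copy()
        flat["value"] = 1.0
        acc = {"T1": 300.0, "T2": 100.0, "T3": 200.0}
        with pytest.warns(UserWarning):
            ranking = composite_rank(flat, {"FBP": True, "NOF": True}, accumulations=acc)
        assert list(ranking.index) == ["T2", "T3", "T1"]

    def test_lower_is_better_direction_flips(self):
        rows = [
            {"treatment_id": t, "index_code": "DEA", "replicate": 1, "value": v}
            for t, v in [("T1", 60.0), ("T2", 20.0)]
        ]
        ranking = composite_rank(pd.DataFrame(rows), {"DEA": False})
        assert list(ranking.index) == ["T2", "T1"]

    def test_saturating_dose_response_picks_first_saturated(self):
        # brute-force oracle over a synthetic saturating table
        doses = {"T1": 0.0, "T2": 200.0, "T3": 400.0, "T4": 600.0}
        response = {t: min(1.0, d / 350.0) for t, d in doses.items()}
        rows = [
            {"treatment_id": t, "index_code": "FBP", "replicate": r, "value": 100 * response[t]}
            for t in doses
            for r in (1, 2)
        ]
        ranking = composite_rank(pd.DataFrame(rows), {"FBP": True}, accumulations=doses)
        best_expected = min(
            (t for t in doses if response[t] == max(response.values())),
            key=lambda t: doses[t],
        )
        assert ranking.index[0] == best_expected == "T3"


class TestReverseUse:
    def test_published_key_points_give_published_fulfillment(self):
        cp12 = load_checkpoint_series("2012-2013")
        cp15 = load_checkpoint_series("2015-2016")
        assert estimate_fulfillment(cp12, 672.0) == pd.Timestamp("2013-01-21")
        assert estimate_fulfillment(cp15, 672.0) == pd.Timestamp("2016-02-04")
        days, weeks = fulfillment_delay(cp12, cp15, 672.0)
        assert (days, weeks) == (14, 2)

    def test_zero_cr_fulfills_at_first_checkpoint(self):
        cp = load_checkpoint_series("2012-2013")
        assert estimate_fulfillment(cp, 0.0) == cp.index[0]

    def test_unreachable_cr_returns_none_and_delay_errors(self):
        cp = load_checkpoint_series("2012-2013")
        assert estimate_fulfillment(cp, 5000.0) is None
        with pytest.raises(UndefinedDelayError):
            fulfillment_delay(cp, cp, 5000.0)

    def test_identical_winters_have_zero_delay(self):
        cp = load_checkpoint_series("2012-2013")
        assert fulfillment_delay(cp, cp, 672.0) == (0, 0)

    def test_fulfillment_monotone_in_cr(self):
        cp = load_checkpoint_series("2015-2016")
        dates = [estimate_fulfillment(cp, cr) for cr in (0, 100, 300, 600, 900, 1084)]
        assert all(
            a <= b for a, b in zip(dates, dates[1:]) if a is not None and b is not None
        )

    def test_precomputed_and_on_demand_checkpoints_agree(self):
        winter = simulate_winter(WinterConfig(seed=11))
        model = ChillHourModel()
        start = detect_start_date(winter, 7.2)
        dates = pd.date_range(start + pd.Timedelta(days=10), periods=6, freq="14D")
        precomputed = pd.Series(
            [hourly_accumulate(winter, (start, d), model) for d in dates], index=dates
        )
        cr = float(precomputed.iloc[3] * 0.9)
        on_demand = {
            d: hourly_accumulate(winter, (start, d), model) for d in dates
        }
        assert estimate_fulfillment(precomputed, cr) == estimate_fulfillment(on_demand, cr)
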