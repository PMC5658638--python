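import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from effortrisk.claims_io import FACTORS, EffortWeights
from effortrisk.datasets import published_totals
from effortrisk.effort_scoring import (
    component_scores,
    effort_risk_score,
    factor_correlations,
    rank_diagnoses,
)
from effortrisk.errors import InsufficientDataError, ParameterError
from effortrisk.rounding import round_half_up


def averages_frame(label, means):
    return pd.DataFrame(
        [dict(diagnosis=label, **{f"mean_{f}": m for f, m in zip(FACTORS, means)})]
    )


KNEE = (2.14, 4.48, 0.57, 7.11, 0.65, 1.72)


class TestComponents:
    def test_out_of_network_component_of_worked_example(self, panel_weights):
        comp = component_scores(averages_frame("knee", KNEE), panel_weights)
        assert comp["component_out_of_network"].iloc[0] == pytest.approx(0.3584)
        assert round_half_up(comp["component_out_of_network"].iloc[0]) == 0.36

    def test_zero_weight_kills_any_mean(self):
        weights = EffortWeights(100, 0, 0, 0, 0, 0)
        comp = component_scores(averages_frame("x", (9, 9, 9, 9, 0.5, 9)), weights)
        assert comp["component_denials"].iloc[0] == 0.0
        assert comp["component_calls"].iloc[0] == pytest.approx(0.5)

    def test_denials_component_keeps_full_precision(self, panel_weights):
        comp = component_scores(averages_frame("knee", KNEE), panel_weights)
        assert comp["component_denials"].iloc[0] == pytest.approx(1.7775)

    def test_negative_mean_rejected(self, panel_weights):
        with pytest.raises(ParameterError):
            component_scores(averages_frame("x", (1, 1, -1, 1, 1, 1)), panel_weights)


class TestEffortRiskScore:
    def test_worked_example_total_renders_two_eighty(self, panel_weights):
        scored = effort_risk_score(averages_frame("knee", KNEE), panel_weights)
        assert scored["total"].iloc[0] == pytest.approx(2.8008)
        assert round_half_up(scored["total"].iloc[0]) == 2.80

    def test_all_zero_averages_score_zero(self, panel_weights):
        scored = effort_risk_score(averages_frame("x", (0,) * 6), panel_weights)
        assert scored["total"].iloc[0] == 0.0

    def test_chronic_kidney_disease_total(self, panel_weights):
        ckd = (1.61, 7.10, 1.38, 15.87, 0.57, 1.13)
        scored = effort_risk_score(averages_frame("ckd", ckd), panel_weights)
        assert round_half_up(scored["total"].iloc[0]) == 5.11

    def test_published_rows_reproduce_within_rounding(
        self, panel_weights, published_averages
    ):
        """Every published total reproduces to the printed value or within
        0.01 of it (the source computed totals from unrounded averages)."""
        scored = effort_risk_score(published_averages, panel_weights)
        printed = published_totals()
        for label, total in zip(scored["diagnosis"], scored["total"]):
            assert abs(round_half_up(total) - printed[label]) <= 0.01 + 1e-12

    @given(
        means=st.lists(st.floats(0, 50), min_size=6, max_size=6),
        scale=st.floats(0.1, 10),
        delta=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_linearity_and_monotonicity(self, panel_weights, means, scale, delta):
        base = effort_risk_score(averages_frame("x", means), panel_weights)
        total = base["total"].iloc[0]
        scaled = effort_risk_score(
            averages_frame("x", [m * scale for m in means]), panel_weights
        )["total"].iloc[0]
        assert scaled == pytest.approx(total * scale, rel=1e-9, abs=1e-9)
        bumped_means = list(means)
        bumped_means[3] += delta  # denials
        bumped = effort_risk_score(
            averages_frame("x", bumped_means), panel_weights
        )["total"].iloc[0]
        assert bumped - total == pytest.approx(0.25 * delta, abs=1e-9)

    @given(means=st.lists(st.floats(0, 100), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_total_is_sum_of_components(self, panel_weights, means):
        scored = effort_risk_score(averages_frame("x", means), panel_weights)
        comp_sum = sum(
            scored[f"component_{f}"].iloc[0] for f in FACTORS
        )
        assert abs(scored["total"].iloc[0] - comp_sum) <= 1e-12


class TestRankDiagnoses:
    @staticmethod
    def _scores(totals):
        frame = pd.DataFrame(
            [dict(code=c, **{f"mean_{f}": 0.0 for f in FACTORS}) for c in totals]
        )
        frame["total"] = list(totals.values())
        return frame

    def test_descending_with_truncation(self):
        ranked = rank_diagnoses(self._scores({"A": 5.11, "B": 3.91, "C": 2.80}), 2)
        assert list(ranked["code"]) == ["A", "B"]

    def test_single_score_is_itself(self):
        ranked = rank_diagnoses(self._scores({"Z": 1.0}))
        assert list(ranked["code"]) == ["Z"]

    def test_ties_break_lexicographically(self):
        ranked = rank_diagnoses(self._scores({"B": 2.0, "A": 2.0, "C": 3.0}))
        assert list(ranked["code"]) == ["C", "A", "B"]

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_top_n_rejected(self, bad):
        with pytest.raises(ParameterError):
            rank_diagnoses(self._scores({"A": 1.0}), bad)


def counts_frame(columns):
    frame = pd.DataFrame(columns)
    frame.insert(0, "household_id", [f"H{i}" for i in range(len(frame))])
    return frame


class TestFactorCorrelations:
    def test_duplicated_factor_correlates_perfectly(self):
        vals = [1, 5, 2, 7]
        counts = counts_frame(
            {
                "n_members_with_claims": vals,
                "n_out_of_network": vals,
                "n_adjustments": [1, 2, 3, 4],
                "n_denials": [2, 2, 3, 9],
                "n_phone": [0, 1, 0, 2],
                "n_web_mobile": [1, 0, 2, 1],
            }
        )
        corr = factor_correlations(counts)
        assert corr.loc["household", "out_of_network"] == pytest.approx(1.0)

    def test_constant_factor_flagged_undefined(self, caplog):
        counts = counts_frame(
            {
                "n_members_with_claims": [2, 2, 2],
                "n_out_of_network": [1, 2, 3],
                "n_adjustments": [3, 1, 2],
                "n_denials": [1, 0, 2],
                "n_phone": [0, 1, 2],
                "n_web_mobile": [2, 1, 0],
            }
        )
        with caplog.at_level("WARNING"):
            corr = factor_correlations(counts)
        assert "household" in caplog.text
        assert np.isnan(corr.loc["household", "denials"])
        assert corr.loc["household", "household"] == 1.0

    def test_anti_monotone_pair_is_minus_one(self):
        counts = counts_frame(
            {
                "n_members_with_claims": [1, 2, 1, 2],
                "n_out_of_network": [0, 1, 1, 0],
                "n_adjustments": [1, 1, 0, 0],
                "n_denials": [1, 2, 3, 4],
                "n_phone": [4, 3, 2, 1],
                "n_web_mobile": [0, 2, 1, 1],
            }
        )
        corr = factor_correlations(counts)
        assert corr.loc["denials", "calls"] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        counts = counts_frame(
            {
                col: rng.poisson(2, 40)
                for col in (
                    "n_members_with_claims", "n_out_of_network", "n_adjustments",
                    "n_denials", "n_phone", "n_web_mobile",
                )
            }
        )
        corr = factor_correlations(counts)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert ((corr.to_numpy() >= -1 - 1e-12) & (corr.to_numpy() <= 1 + 1e-12)).all()

    def test_fewer_than_three_households_rejected(self):
        counts = counts_frame(
            {
                "n_members_with_claims": [1, 2],
                "n_out_of_network": [0, 1],
                "n_adjustments": [1, 0],
                "n_denials": [1, 2],
                "n_phone": [0, 1],
                "n_web_mobile": [1, 0],
            }
        )
        with pytest.raises(InsufficientDataError):
            factor_correlations(counts)

    def test_spearman_method_available(self):
        counts = counts_frame(
            {
                "n_members_with_claims": [1, 2, 3, 4],
                "n_out_of_network": [1, 4, 9, 16],
                "n_adjustments": [0, 1, 2, 3],
                "n_denials": [1, 2, 3, 5],
                "n_phone": [0, 1, 2, 4],
                "n_web_mobile": [1, 2, 3, 4],
            }
        )
        corr = factor_correlations(counts, method="spearman")
        # perfectly monotone pair: rank correlation 1 even though nonlinear
        assert corr.loc["household", "out_of_network"] == pytest.approx(1.0)
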