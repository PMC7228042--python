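"""Validation metrics: discrimination, calibration, risk groups, net benefit."""

import numpy as np
import pandas as pd
import pytest

from endorisk.validation import (
    RISK_GROUP_EDGES,
    RiskGroupTable,
    ScoredOutcomes,
    assign_risk_group,
    auc,
    brier,
    calibration_table,
    cutoff_metrics,
    decision_curve,
    pool_risk_table,
    predicted_observed_ratio,
    risk_group_table,
)


def _random_scored(seed: int, n: int = 300) -> ScoredOutcomes:
    rng = np.random.default_rng(seed)
    p = rng.random(n)
    y = (rng.random(n) < p).astype(int)
    return ScoredOutcomes(p, y)


def brute_force_auc(scored: ScoredOutcomes) -> float:
    """All-pairs concordance with half credit for ties (naive loop)."""
    pos = scored.probabilities[scored.outcomes == 1]
    neg = scored.probabilities[scored.outcomes == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_four_point_concordance(self):
        scored = ScoredOutcomes([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc(scored)["auc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        scored = ScoredOutcomes([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc(scored)["auc"] == 1.0

    def test_all_ties_give_half(self):
        scored = ScoredOutcomes([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert auc(scored)["auc"] == pytest.approx(0.5, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            auc(ScoredOutcomes([0.2, 0.4], [1, 1]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_concordance(self, seed):
        scored = _random_scored(seed, n=150)
        assert auc(scored)["auc"] == pytest.approx(
            brute_force_auc(scored), abs=1e-12
        )

    def test_delong_ci_brackets_estimate_and_shrinks(self):
        small = auc(_random_scored(3, n=100))
        large = auc(_random_scored(3, n=2_000))
        for res in (small, large):
            assert res["ci_low"] <= res["auc"] <= res["ci_high"]
        assert (large["ci_high"] - large["ci_low"]) < (
            small["ci_high"] - small["ci_low"]
        )

    def test_bootstrap_ci_close_to_delong(self):
        scored = _random_scored(4, n=400)
        d = auc(scored, ci_method="delong")
        b = auc(scored, ci_method="bootstrap")
        assert d["ci_low"] == pytest.approx(b["ci_low"], abs=0.03)
        assert d["ci_high"] == pytest.approx(b["ci_high"], abs=0.03)


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        scored = ScoredOutcomes([0.0, 1.0, 1.0], [0, 1, 1])
        assert brier(scored) == 0.0

    def test_constant_half_scores_quarter(self):
        scored = ScoredOutcomes([0.5] * 5, [0, 1, 1, 0, 1])
        assert brier(scored) == pytest.approx(0.25, abs=1e-15)

    def test_calibrated_constant_closed_form(self):
        """Brier of the constant prevalence prediction equals pi(1-pi)."""
        y = np.array([1] * 30 + [0] * 70)
        pi = y.mean()
        scored = ScoredOutcomes(np.full(100, pi), y)
        assert brier(scored) == pytest.approx(pi * (1 - pi), abs=1e-12)

    def test_matches_naive_loop(self):
        scored = _random_scored(5)
        naive = sum(
            (p - o) ** 2 for p, o in zip(scored.probabilities, scored.outcomes)
        ) / len(scored)
        assert brier(scored) == pytest.approx(naive, abs=1e-15)


class TestCalibration:
    def test_groupwise_perfect_calibration(self):
        p = np.repeat([0.2, 0.8], 50)
        y = np.concatenate([np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)]).astype(int)
        table = calibration_table(ScoredOutcomes(p, y), n_bins=2)
        for _, row in table.iterrows():
            assert row["observed_rate"] == pytest.approx(row["mean_predicted"])

    def test_identical_predictions_merge_to_one_bin(self):
        scored = ScoredOutcomes([0.4] * 30, [0] * 20 + [1] * 10)
        table = calibration_table(scored)
        assert len(table) == 1 and table.loc[0, "count"] == 30

    def test_counts_conserved_and_matches_rebinning_oracle(self):
        scored = _random_scored(6, n=500)
        table = calibration_table(scored, n_bins=10)
        assert table["count"].sum() == 500
        edges = np.unique(np.quantile(scored.probabilities, np.linspace(0, 1, 11)))
        idx = np.clip(
            np.searchsorted(edges, scored.probabilities, side="right") - 1,
            0,
            len(edges) - 2,
        )
        for k, (_, row) in enumerate(table.iterrows()):
            mask = idx == k
            assert row["count"] == mask.sum()
            assert row["observed_rate"] == pytest.approx(scored.outcomes[mask].mean())


class TestPredictedObservedRatio:
    def test_indicator_predictions_give_unity(self):
        y = np.array([0, 1, 1, 0, 1])
        scored = ScoredOutcomes(y.astype(float), y)
        assert predicted_observed_ratio(scored)["ratio"] == pytest.approx(1.0)

    def test_scaling_property(self):
        scored = _random_scored(7)
        half = ScoredOutcomes(scored.probabilities / 2, scored.outcomes)
        r_full = predicted_observed_ratio(scored)["ratio"]
        r_half = predicted_observed_ratio(half)["ratio"]
        assert r_half == pytest.approx(r_full / 2)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            predicted_observed_ratio(ScoredOutcomes([0.3, 0.2], [0, 0]))

    def test_self_consistent_predictions_within_ci(self):
        scored = _random_scored(8, n=800)  # outcomes drawn from the predictions
        res = predicted_observed_ratio(scored, seed=9)
        assert res["ci_low"] <= 1.0 <= res["ci_high"]


class TestCutoffMetrics:
    def test_cutoff_zero_all_positive(self):
        scored = _random_scored(10)
        m = cutoff_metrics(scored, 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_cutoff_above_all_scores_gives_npv_one_minus_prevalence(self):
        scored = ScoredOutcomes([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        m = cutoff_metrics(scored, 1.0)
        assert m["tp"] + m["fp"] == 0
        assert m["npv"] == pytest.approx(1 - scored.prevalence)

    def test_ties_count_as_positive(self):
        scored = ScoredOutcomes([0.5, 0.5], [1, 0])
        m = cutoff_metrics(scored, 0.5)
        assert m["tp"] == 1 and m["fp"] == 1

    def test_counts_conserve_cohort(self):
        scored = _random_scored(11)
        m = cutoff_metrics(scored, 0.37)
        assert m["tp"] + m["fp"] + m["fn"] + m["tn"] == len(scored)


class TestRiskGroups:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.005, "very_low"),
            (0.03, "low"),
            (0.0099, "very_low"),
            (0.01, "low"),
            (0.05, "intermediate"),
            (0.30, "high"),
            (1.0, "high"),
        ],
    )
    def test_boundary_assignment(self, p, label):
        assert assign_risk_group(p) == label

    def test_degenerate_cohort_single_group(self):
        scored = ScoredOutcomes([0.001] * 20, [0] * 20)
        table = risk_group_table(scored)
        assert table.counts == (20, 0, 0, 0, 0) and table.events == (0, 0, 0, 0, 0)

    def test_counts_conserved(self):
        scored = _random_scored(12, n=700)
        table = risk_group_table(scored)
        assert table.total == 700

    def test_prevalence_monotone_for_model_based_scores(self):
        scored = _random_scored(13, n=5_000)  # outcomes drawn from the scores
        table = risk_group_table(scored)
        prevs = [e / c for e, c in zip(table.events, table.counts) if c > 0]
        assert all(a <= b + 1e-12 for a, b in zip(prevs, prevs[1:]))


# printed risk-group counts of the external validation cohort (n=446):
# (24, 0), (225, 4), (84, 14), (43, 9), (70, 25)
VALIDATION_TABLE = RiskGroupTable(
    counts=(24, 225, 84, 43, 70), events=(0, 4, 14, 9, 25)
)


class TestPoolRiskTable:
    def test_proportion_below_five_percent(self):
        pooled = pool_risk_table(VALIDATION_TABLE, 0.05)
        assert pooled["n_below"] == 249
        assert pooled["proportion_below"] == pytest.approx(249 / 446)
        assert round(100 * pooled["proportion_below"], 1) == 55.8

    def test_false_negative_rate_below(self):
        pooled = pool_risk_table(VALIDATION_TABLE, 0.05)
        assert pooled["fn_rate_below"] == pytest.approx(4 / 249)
        assert round(100 * pooled["fn_rate_below"], 1) == 1.6

    def test_false_discovery_above(self):
        pooled = pool_risk_table(VALIDATION_TABLE, 0.05)
        assert pooled["false_discovery_above"] == pytest.approx(149 / 197)
        assert round(100 * pooled["false_discovery_above"]) == 76

    def test_group_prevalences(self):
        assert VALIDATION_TABLE.prevalence("low") == pytest.approx(4 / 225)
        assert VALIDATION_TABLE.prevalence("intermediate") == pytest.approx(14 / 84)
        assert VALIDATION_TABLE.prevalence("high") == pytest.approx(25 / 70)

    def test_boundary_must_be_group_edge(self):
        with pytest.raises(ValueError, match="edge"):
            pool_risk_table(VALIDATION_TABLE, 0.10)


class TestDecisionCurve:
    def test_treat_all_crosses_zero_at_prevalence(self):
        scored = _random_scored(14, n=400)
        pi = scored.prevalence
        curve = decision_curve(scored, [pi])
        assert curve.treat_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.array([0] * 60 + [1] * 40)
        scored = ScoredOutcomes(y.astype(float), y)
        curve = decision_curve(scored, np.linspace(0.05, 0.9, 10))
        np.testing.assert_allclose(curve.model, scored.prevalence, atol=1e-12)

    def test_model_equals_treat_all_below_min_score(self):
        scored = _random_scored(15)
        t = scored.probabilities.min() / 2 + 1e-9
        curve = decision_curve(scored, [t])
        assert curve.model[0] == pytest.approx(curve.treat_all[0], abs=1e-12)

    def test_net_benefit_never_exceeds_prevalence(self):
        scored = _random_scored(16)
        curve = decision_curve(scored, np.linspace(0.01, 0.95, 40))
        assert (curve.model <= scored.prevalence + 1e-12).all()

    def test_matches_naive_loop_oracle(self):
        scored = _random_scored(17, n=250)
        grid = np.linspace(0.05, 0.6, 12)
        curve = decision_curve(scored, grid)
        n = len(scored)
        for k, t in enumerate(grid):
            tp = sum(
                1 for p, y in zip(scored.probabilities, scored.outcomes) if p >= t and y
            )
            fp = sum(
                1
                for p, y in zip(scored.probabilities, scored.outcomes)
                if p >= t and not y
            )
            expected = tp / n - (fp / n) * t / (1 - t)
            assert curve.model[k] == pytest.approx(expected, abs=1e-12)

    def test_thresholds_must_be_interior(self):
        scored = _random_scored(18)
        with pytest.raises(ValueError, match="strictly"):
            decision_curve(scored, [0.0, 0.5])
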