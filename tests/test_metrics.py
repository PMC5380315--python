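"""Validation metrics: AUC against a pair-counting oracle, calibration
recovery on simulated miscalibration, classification counts/CIs and
count-matched threshold selection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, logit

from lungrisk import cohort_frame, get_model
from lungrisk.cohort import nlst_eligible
from lungrisk.metrics import (
    auc,
    calibration_groups,
    calibration_intercept_slope,
    match_threshold_to_count,
    sens_spec,
)
from lungrisk import synth


def _pair_counting_auc(scores, labels):
    """O(n^2) concordance oracle: ties count 1/2."""
    cases = scores[labels]
    controls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAUC:
    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            # discrete scores force ties regularly
            scores = rng.integers(0, 8, size=n).astype(float)
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels).auc == pytest.approx(
                _pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_perfect_separation_is_one(self):
        assert auc([0.9, 0.1], [True, False]).auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.3] * 10, [True] * 4 + [False] * 6).auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="class"):
            auc([0.2, 0.4], [True, True])

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = rng.random(200) < scores
        a1 = auc(scores, labels)
        a2 = auc(np.exp(5 * scores), labels)
        assert a1.auc == pytest.approx(a2.auc, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        scores = rng.random(500)
        labels = rng.random(500) < scores
        res = auc(scores, labels)
        assert res.ci_lower <= res.auc <= res.ci_upper
        assert res.n_cases + res.n_controls == 500


class TestCalibrationGroups:
    def test_constant_predictions_single_group_point(self):
        p = np.full(1000, 0.3)
        rng = np.random.default_rng(0)
        y = rng.random(1000) < 0.3
        with pytest.warns(UserWarning):
            groups = calibration_groups(p, y, n_groups=10)
        assert len(groups) == 1
        assert groups[0].mean_predicted == pytest.approx(0.3)
        assert groups[0].observed_proportion == pytest.approx(y.mean())

    def test_all_negative_outcomes_give_zero_proportions(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.2, 500)
        groups = calibration_groups(p, np.zeros(500, dtype=bool))
        assert all(g.observed_proportion == 0.0 for g in groups)
        assert sum(g.n for g in groups) == 500

    def test_well_calibrated_predictions_hug_the_diagonal(self):
        rng = np.random.default_rng(2)
        p = expit(rng.normal(-2.0, 1.0, 10_000))
        y = rng.random(10_000) < p
        for g in calibration_groups(p, y):
            se = np.sqrt(g.mean_predicted * (1 - g.mean_predicted) / g.n)
            assert abs(g.observed_proportion - g.mean_predicted) <= 3 * se + 1e-9


class TestCalibrationInterceptSlope:
    def test_correct_predictions_recover_identity(self):
        rng = np.random.default_rng(3)
        p = expit(rng.normal(-2.5, 1.2, 50_000))
        y = rng.random(50_000) < p
        intercept, slope, intercept_joint, flag = calibration_intercept_slope(p, y)
        assert not flag
        assert intercept == pytest.approx(0.0, abs=0.05)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept_joint == pytest.approx(0.0, abs=0.06)

    def test_doubled_logits_halve_the_slope(self):
        rng = np.random.default_rng(4)
        p = expit(rng.normal(-2.0, 1.0, 50_000))
        doubled = expit(2.0 * logit(p))
        y = rng.random(50_000) < p  # truth follows p, predictions are 'doubled'
        _, slope, _, _ = calibration_intercept_slope(doubled, y)
        assert slope == pytest.approx(0.5, abs=0.04)

    def test_shifted_outcome_logodds_recovered_in_the_large(self):
        rng = np.random.default_rng(5)
        p = expit(rng.normal(-2.5, 1.0, 50_000))
        y = rng.random(50_000) < expit(logit(p) + 1.0)
        intercept, _, _, _ = calibration_intercept_slope(p, y)
        assert intercept == pytest.approx(1.0, abs=0.06)

    def test_perfect_separation_flagged(self):
        p = np.array([0.9] * 5 + [0.1] * 5)
        y = np.array([True] * 5 + [False] * 5)
        *_, flag = calibration_intercept_slope(p, y)
        assert flag


class TestSensSpec:
    def test_counts_arithmetic(self):
        flags = np.array([True] * 460 + [False] * 640)
        outcomes = np.array([True] * 80 + [False] * 380 + [True] * 20 + [False] * 620)
        res = sens_spec(flags, outcomes)
        assert (res.tp, res.fp, res.fn, res.tn) == (80, 380, 20, 620)
        assert res.sensitivity == pytest.approx(0.80)
        assert res.specificity == pytest.approx(0.62)
        assert res.sensitivity_ci[0] < 0.80 < res.sensitivity_ci[1]

    def test_flag_everyone(self):
        res = sens_spec([True, True, True], [True, False, True])
        assert res.sensitivity == 1.0 and res.specificity == 0.0

    def test_no_cases_leaves_sensitivity_undefined(self):
        res = sens_spec([True, False], [False, False])
        assert res.sensitivity is None and res.sensitivity_ci is None
        assert res.specificity is not None

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        p = rng.random(2000)
        y = rng.random(2000) < p
        prev_sens, prev_spec = 1.1, -0.1
        for t in np.linspace(0.05, 0.95, 10):
            res = sens_spec(p >= t, y)
            assert res.sensitivity <= prev_sens + 1e-12
            assert res.specificity >= prev_spec - 1e-12
            prev_sens, prev_spec = res.sensitivity, res.specificity


class TestMatchThreshold:
    def test_order_statistic(self):
        res = match_threshold_to_count([0.9, 0.5, 0.1], 2)
        assert res.threshold == 0.5 and res.realized_count == 2 and not res.tied

    def test_all_tied_includes_everyone(self):
        with pytest.warns(UserWarning, match="ties"):
            res = match_threshold_to_count([0.2, 0.2, 0.2, 0.2], 1)
        assert res.realized_count == 4 and res.tied

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            match_threshold_to_count([0.1, 0.2], 3)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(9)
        p = rng.random(10_000)
        res = match_threshold_to_count(p, 3000)
        # brute force: smallest observed threshold selecting <= 3000
        candidates = np.sort(np.unique(p))[::-1]
        counts = [(t, (p >= t).sum()) for t in candidates]
        best = min((t for t, c in counts if c <= 3000))
        assert res.threshold == pytest.approx(best)
        assert res.realized_count == (p >= res.threshold).sum() <= 3000 + 1


class TestGeneratingModelDominance:
    @pytest.mark.parametrize("model_id", ["plcom2012", "llp"])
    def test_true_model_beats_criteria_at_matched_count(self, model_id):
        """When outcomes are generated from model M, M's count-matched
        sensitivity is at least the pack-year criteria's (2-SE slack)."""
        subs = synth.generate_cohort(synth.plco_like(20_000), seed=31)
        outs = synth.simulate_outcomes(
            subs, synth.OutcomeSimSpec(generating_model=model_id, seed=32)
        )
        y = np.array([o.lc_incidence for o in outs])
        flags = np.array([bool(nlst_eligible(s)) for s in subs])
        p = get_model(model_id).risk_vector(cohort_frame(subs), 6.0)
        matched = match_threshold_to_count(p, int(flags.sum()))
        sens_model = sens_spec(p >= matched.threshold, y).sensitivity
        crit = sens_spec(flags, y)
        se = np.sqrt(crit.sensitivity * (1 - crit.sensitivity) / y.sum())
        assert sens_model >= crit.sensitivity - 2 * se

    def test_generating_model_auc_tops_other_models(self):
        """The true model discriminates at least as well as the rest
        (2-SE slack)."""
        subs = synth.generate_cohort(synth.plco_like(20_000), seed=33)
        outs = synth.simulate_outcomes(subs, synth.OutcomeSimSpec(seed=34))
        y = np.array([o.lc_incidence for o in outs])
        df = cohort_frame(subs)
        true_auc = auc(get_model("plcom2012").risk_vector(df, 6.0), y)
        se = (true_auc.ci_upper - true_auc.ci_lower) / (2 * 1.959964)
        for other in ("bach", "llp", "knoke", "tsce_incidence"):
            other_auc = auc(get_model(other).risk_vector(df, 6.0), y).auc
            assert true_auc.auc >= other_auc - 2 * se
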