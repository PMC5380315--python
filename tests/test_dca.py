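"""Decision-curve analysis: weighting-factor arithmetic, net-benefit
identities, curve dominance, and threshold-range detection."""

from __future__ import annotations

import numpy as np
import pytest

from lungrisk.dca import (
    DEFAULT_GRID,
    decision_curve,
    harm_ratio,
    interpret_nb_delta,
    net_benefit,
    positive_nb_range,
    threshold_odds,
)
from lungrisk.metrics import sens_spec

# (printed threshold, printed weighting factor) pairs from the published
# positive-net-benefit threshold table: 9 models x 4 cohorts x lower/upper.
PUBLISHED_THRESHOLD_WF_CELLS = [
    (0.005, 199.0), (0.127, 6.9), (0.009, 110.1), (0.135, 6.4),
    (0.003, 332.3), (0.104, 8.6), (0.002, 499.0), (0.089, 10.2),
    (0.018, 54.6), (0.080, 11.5), (0.012, 82.3), (0.073, 12.7),
    (0.004, 249.0), (0.065, 14.4), (0.004, 249.0), (0.058, 16.2),
    (0.019, 51.6), (0.085, 10.8), (0.019, 51.6), (0.085, 10.8),
    (0.004, 249.0), (0.085, 10.8), (0.003, 332.3), (0.053, 17.9),
    (0.009, 110.1), (0.161, 5.2), (0.001, 999.0), (0.105, 8.5),
    (0.002, 499.0), (0.090, 10.1), (0.001, 999.0), (0.110, 8.1),
    (0.007, 141.9), (0.136, 6.4), (0.007, 141.9), (0.120, 7.3),
    (0.003, 332.3), (0.093, 9.8), (0.002, 499.0), (0.085, 10.8),
    (0.020, 49.0), (0.121, 7.3), (0.011, 89.9), (0.080, 11.5),
    (0.003, 332.3), (0.079, 11.7), (0.002, 499.0), (0.069, 13.5),
    (0.035, 27.6), (0.133, 6.5), (0.028, 34.7), (0.088, 10.4),
    (0.030, 32.3), (0.077, 12.0), (0.029, 33.5), (0.072, 12.9),
    (0.034, 28.4), (0.071, 13.1), (0.028, 34.7), (0.062, 15.1),
    (0.028, 34.7), (0.062, 15.1), (0.028, 34.7), (0.060, 15.7),
    (0.027, 36.0), (0.167, 5.0), (0.020, 49.0), (0.099, 9.1),
    (0.002, 499.0), (0.078, 11.8), (0.023, 42.5), (0.066, 14.2),
]


class TestWeightingFactors:
    def test_two_and_a_half_percent_worked_example(self):
        assert threshold_odds(0.025) == pytest.approx(1.0 / 39.0, rel=1e-12)
        assert harm_ratio(0.025) == pytest.approx(39.0, rel=1e-12)
        # one case detected per 40 screened persons
        assert harm_ratio(0.025) + 1 == pytest.approx(40.0, rel=1e-12)

    @pytest.mark.parametrize("t, wf", [(0.005, 199.0), (0.001, 999.0), (0.5, 1.0)])
    def test_printed_harm_ratios(self, t, wf):
        assert round(harm_ratio(t), 1) == wf

    def test_all_published_table_cells_reproduce(self):
        for t, wf in PUBLISHED_THRESHOLD_WF_CELLS:
            assert round(harm_ratio(t), 1) == pytest.approx(wf), (t, wf)

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, t):
        with pytest.raises(ValueError):
            threshold_odds(t)


class TestNetBenefit:
    def test_screen_none_is_zero(self):
        y = np.array([True, False, False, True])
        nb = net_benefit(np.zeros(4, dtype=bool), y, 0.05)
        assert nb.net_benefit == 0.0 and nb.tp == nb.fp == 0

    def test_screen_all_identity(self):
        rng = np.random.default_rng(0)
        y = rng.random(5000) < 0.1
        pi = y.mean()
        t = 0.03
        nb = net_benefit(np.ones(len(y), dtype=bool), y, t)
        assert nb.net_benefit == pytest.approx(pi - (1 - pi) * t / (1 - t), abs=1e-12)

    def test_worked_hand_value(self):
        flags = np.array([True] * 500 + [False] * 500)
        y = np.array([True] * 30 + [False] * 470 + [False] * 500)
        nb = net_benefit(flags, y, 0.025)
        assert (nb.tp, nb.fp, nb.n) == (30, 470, 1000)
        assert nb.net_benefit == pytest.approx((30 - 470 / 39) / 1000, rel=1e-12)
        assert nb.net_benefit == pytest.approx(0.0179487179, abs=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            net_benefit([], [], 0.1)

    def test_consistency_with_sensitivity_specificity_decomposition(self):
        """NB from counts equals sens*pi - (1-spec)(1-pi) * odds(t)."""
        rng = np.random.default_rng(1)
        p = rng.random(2000)
        y = rng.random(2000) < p * 0.3
        pi = y.mean()
        for t in (0.01, 0.05, 0.1, 0.2):
            flags = p >= t
            nb = net_benefit(flags, y, t).net_benefit
            cls = sens_spec(flags, y)
            expected = cls.sensitivity * pi - (1 - cls.specificity) * (1 - pi) * t / (1 - t)
            assert nb == pytest.approx(expected, abs=1e-12)


class TestDecisionCurve:
    def test_perfect_test_dominates_any_comparator(self):
        rng = np.random.default_rng(2)
        y = rng.random(1000) < 0.2
        p = np.where(y, 0.99, 0.01)
        comparator = rng.random(1000) < 0.5
        points = decision_curve(p, y, comparator, grid=np.arange(0.02, 0.99, 0.02))
        by_t = {}
        for pt in points:
            by_t.setdefault(pt.threshold, {})[pt.strategy] = pt.net_benefit
        for t, row in by_t.items():
            assert row["model"] >= row["comparator"] - 1e-12
            assert row["model"] >= row["screen_all"] - 1e-12
            assert row["model"] >= row["screen_none"] - 1e-12

    def test_single_point_grid_reduces_to_net_benefit(self):
        rng = np.random.default_rng(3)
        p = rng.random(300)
        y = rng.random(300) < p
        points = decision_curve(p, y, None, grid=[0.1])
        model_pt = [pt for pt in points if pt.strategy == "model"][0]
        direct = net_benefit(p >= 0.1, y, 0.1)
        assert model_pt.net_benefit == direct.net_benefit

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            decision_curve([0.5], [True], None, grid=[0.2, 0.1])


class TestPositiveRange:
    def test_identical_strategies_have_no_strict_improvement(self):
        y = np.array([True] * 50 + [False] * 450)
        flags = np.array([True] * 100 + [False] * 400)
        p = np.where(flags, 0.9, 0.001)  # model == comparator at any t in between
        rng_res = positive_nb_range(p, y, flags, grid=np.arange(0.01, 0.5, 0.01))
        assert rng_res.empty or rng_res.lower == rng_res.upper

    def test_any_informative_model_beats_screen_none_from_grid_minimum(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 0.5, 2000)
        y = rng.random(2000) < p
        none = np.zeros(2000, dtype=bool)
        rng_res = positive_nb_range(p, y, none)
        assert rng_res.lower == pytest.approx(DEFAULT_GRID[0])

    def test_model_vs_criteria_range_is_contiguous(self):
        from lungrisk import synth, cohort_frame, get_model
        from lungrisk.cohort import nlst_eligible

        subs = synth.generate_cohort(synth.plco_like(10_000), seed=41)
        outs = synth.simulate_outcomes(subs, synth.OutcomeSimSpec(seed=42))
        y = np.array([o.lc_incidence for o in outs])
        flags = np.array([bool(nlst_eligible(s)) for s in subs])
        p = get_model("plcom2012").risk_vector(cohort_frame(subs), 6.0)
        res = positive_nb_range(p, y, flags)
        assert not res.empty and res.lower < res.upper
        # contiguity: every grid point between lower and upper is positive
        inner = DEFAULT_GRID[(DEFAULT_GRID >= res.lower) & (DEFAULT_GRID <= res.upper)]
        for t in inner[:: max(len(inner) // 25, 1)]:
            nb_m = net_benefit(p >= t, y, t).net_benefit
            nb_c = net_benefit(flags, y, t).net_benefit
            assert nb_m > nb_c


class TestInterpretation:
    @pytest.mark.parametrize(
        "delta, t, expected",
        [(0.002, 0.025, (2.0, 78.0)), (0.0, 0.1, (0.0, 0.0)), (0.01, 0.5, (10.0, 10.0))],
    )
    def test_worked_examples(self, delta, t, expected):
        tp_gain, fp_red = interpret_nb_delta(delta, t)
        assert tp_gain == pytest.approx(expected[0], rel=1e-12)
        assert fp_red == pytest.approx(expected[1], rel=1e-12)

    def test_fp_reduction_consistent_with_count_recomputation(self):
        """The stated FP-equivalent equals the FP-count change that produces
        the same net-benefit difference at fixed TP."""
        y = np.array([True] * 40 + [False] * 960)
        t = 0.025
        flags_a = np.array([True] * 40 + [True] * 200 + [False] * 760)
        flags_b = np.array([True] * 40 + [True] * 122 + [False] * 838)
        nb_a = net_benefit(flags_a, y, t).net_benefit
        nb_b = net_benefit(flags_b, y, t).net_benefit
        delta = nb_b - nb_a
        _, fp_equiv = interpret_nb_delta(delta, t)
        # per 1000 assessed, with n = 1000 the fp change is exactly 78
        assert fp_equiv == pytest.approx(200 - 122, rel=1e-12)
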