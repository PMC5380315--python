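"""Risk calculators: hand-verifiable values, structural identities, and
shared monotonicity/range properties across all nine registered models."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from lungrisk import Subject, SmokingHistory, build_model, get_model, predict
from lungrisk.cohort import cohort_frame
from lungrisk.models import (
    CovariateDomainError,
    IncompleteCovariateError,
    bach_risk,
    knoke_risk,
    llp_risk,
    plcom2012_logit,
)
from lungrisk.registry import MODEL_IDS, RegistryError

ITERATIVE_MODELS = ("bach", "knoke", "tsce_incidence", "tsce_cps_death",
                    "tsce_nhs_hpfs_death")


def _hand_plcom2012_logit(age, race_coef, edu, bmi, copd, cancer, famhist,
                          current, cpd, duration, ysq):
    """Independent hand computation of the published PLCOm2012 linear
    predictor (constants restated here on purpose, not read from config)."""
    lp = -4.532506
    lp += 0.0778868 * (age - 62)
    lp += race_coef
    lp += -0.0812744 * (edu - 4)
    lp += -0.0274194 * (bmi - 27)
    lp += 0.3553063 * copd
    lp += 0.4589971 * cancer
    lp += 0.587185 * famhist
    lp += 0.2597431 * current
    lp += -1.822606 * ((cpd / 10.0) ** -1 - 0.4021541613)
    lp += 0.0317321 * (duration - 27.6605081)
    lp += -0.0308572 * (ysq - 8.593417626)
    return lp


class TestPLCOm2012:
    def test_centering_identity(self, reference_profile):
        assert plcom2012_logit(reference_profile) == pytest.approx(-4.532506, abs=1e-9)

    def test_copd_shifts_logit_by_its_coefficient(self, moderate_former_smoker):
        with_copd = replace(moderate_former_smoker, copd=True)
        diff = plcom2012_logit(with_copd) - plcom2012_logit(moderate_former_smoker)
        assert diff == pytest.approx(0.3553063, abs=1e-12)

    def test_heavy_current_smoker_matches_hand_calculation(self, heavy_current_smoker):
        lp = _hand_plcom2012_logit(age=70, race_coef=0.0, edu=2, bmi=28, copd=1,
                                   cancer=0, famhist=1, current=1, cpd=30,
                                   duration=55, ysq=0)
        expected = 1.0 / (1.0 + math.exp(-lp))
        got = predict("plcom2012", heavy_current_smoker, 6).probability
        assert got == pytest.approx(expected, abs=1e-12)
        # pinned regression value from the verified hand calculation
        assert got == pytest.approx(0.2118339, abs=1e-6)

    def test_moderate_former_smoker_matches_hand_calculation(self, moderate_former_smoker):
        lp = _hand_plcom2012_logit(age=63, race_coef=0.3944778, edu=5, bmi=25,
                                   copd=0, cancer=0, famhist=0, current=0, cpd=15,
                                   duration=40, ysq=10)
        expected = 1.0 / (1.0 + math.exp(-lp))
        assert predict("plcom2012", moderate_former_smoker, 6).probability == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_intensity_outside_reciprocal_transform_domain(self, reference_profile):
        bad = replace(reference_profile,
                      smoking=replace(reference_profile.smoking, intensity=0.0))
        with pytest.raises(CovariateDomainError, match="smoking_intensity"):
            predict("plcom2012", bad, 6)

    def test_simplified_variant_differs_from_full_model(self, moderate_former_smoker):
        full = predict("plcom2012", moderate_former_smoker, 6).probability
        simple = predict("plcom2012_simplified", moderate_former_smoker, 6).probability
        assert full != simple


def _toy_annual_payload(p_lc: float, p_death: float) -> dict:
    """Annual-cycle payload with constant cycle probabilities (log-hazard
    intercepts chosen so 1 - exp(-exp(lp)) equals the target exactly)."""
    def intercept(p):
        return -1e9 if p == 0 else math.log(-math.log(1.0 - p))

    payload = {
        "model_id": "toy", "outcome": "incidence", "horizon": 6,
        "form": "annual_cycle",
        "lung_cancer_hazard": {"intercept": intercept(p_lc), "terms": {}},
    }
    if p_death is not None:
        payload["competing_death_hazard"] = {
            "intercept": intercept(p_death), "terms": {}
        }
    return payload


class TestAnnualCycleComposition:
    def test_zero_hazard_payload_gives_zero_risk(self, heavy_current_smoker):
        model = build_model(_toy_annual_payload(0.0, 0.0))
        assert model.predict(heavy_current_smoker, 6).probability == 0.0

    def test_single_cycle_equals_annual_probability(self, heavy_current_smoker):
        model = build_model(_toy_annual_payload(0.01, 0.05))
        assert model.predict(heavy_current_smoker, 1).probability == pytest.approx(
            0.01, abs=1e-12
        )

    def test_two_cycle_toy_composition_hand_value(self, heavy_current_smoker):
        model = build_model(_toy_annual_payload(0.01, 0.05))
        # 0.01 + 0.99 * 0.95 * 0.01
        assert model.predict(heavy_current_smoker, 2).probability == pytest.approx(
            0.019405, abs=1e-12
        )

    def test_no_competing_death_reduces_to_cumulative_incidence(self, heavy_current_smoker):
        model = build_model(_toy_annual_payload(0.03, None))
        risk = model.predict(heavy_current_smoker, 6).probability
        assert risk == pytest.approx(1.0 - (1.0 - 0.03) ** 6, abs=1e-12)

    def test_bach_advances_covariates_each_cycle(self, moderate_former_smoker):
        """Freezing covariates (horizon-1 chaining by hand with advancing
        age/quit-years) reproduces the 6-year composition."""
        model = get_model("bach")
        s = moderate_former_smoker
        s_lc = s_death = 1.0
        total = 0.0
        for k in range(6):
            aged = replace(
                s, age=float(math.floor(s.age)) + k,
                smoking=replace(s.smoking,
                                years_since_quit=s.smoking.years_since_quit + k),
            )
            df = cohort_frame([aged])
            p_lc = 1.0 - math.exp(-math.exp(_bach_lp(model, df, "lung_cancer_hazard")))
            p_d = 1.0 - math.exp(-math.exp(_bach_lp(model, df, "competing_death_hazard")))
            total += s_lc * s_death * p_lc
            s_lc *= 1 - p_lc
            s_death *= 1 - p_d
        assert model.predict(s, 6).probability == pytest.approx(total, rel=1e-9)


def _bach_lp(model, df, which):
    from lungrisk.models import _linear_predictor

    cfg = model.payload[which]
    return float(_linear_predictor(df, cfg["intercept"], cfg["terms"])[0])


class TestLLP:
    def test_reference_level_gives_baseline_risk(self):
        model = get_model("llp")
        s = Subject(id="r", age=67, gender="male", personal_history_cancer=False,
                    family_history_lc=False, history_pneumonia=False, asbestos=False,
                    smoking=SmokingHistory(status="former", duration=0.0,
                                           intensity=0.0, years_since_quit=5.0))
        base = model.payload["baseline_risk"]["male"][5]  # 65-70 band
        assert model.predict(s).probability == pytest.approx(base, abs=1e-12)

    def test_risk_increases_across_duration_categories(self, light_former_smoker):
        model = get_model("llp")
        risks = []
        for duration in (10, 30, 50):
            s = replace(light_former_smoker,
                        smoking=replace(light_former_smoker.smoking, duration=duration))
            risks.append(model.predict(s).probability)
        assert risks[0] < risks[1] < risks[2]

    def test_asbestos_ignored_by_default_assumption(self, light_former_smoker):
        model = get_model("llp")
        no_asb = replace(light_former_smoker, asbestos=False)
        assert model.predict(light_former_smoker).probability == model.predict(
            no_asb
        ).probability


class TestKnoke:
    def test_zero_hazard_payload_gives_zero(self, heavy_current_smoker):
        payload = dict(get_model("knoke").payload)
        payload["lung_cancer_hazard"] = {"intercept": -1e9, "terms": {}}
        assert build_model(payload).predict(heavy_current_smoker, 6).probability == 0.0

    def test_horizon_one_is_single_year_hazard_conversion(self, heavy_current_smoker):
        model = get_model("knoke")
        df = cohort_frame([heavy_current_smoker])
        df["age"] = np.floor(df["age"])
        lp = _bach_lp(model, df, "lung_cancer_hazard")
        assert model.predict(heavy_current_smoker, 1).probability == pytest.approx(
            1.0 - math.exp(-math.exp(lp)), rel=1e-12
        )


class TestDispatch:
    def test_unknown_model_id_is_registry_error(self, heavy_current_smoker):
        with pytest.raises(RegistryError):
            predict("no_such_model", heavy_current_smoker, 6)

    def test_missing_covariate_named_in_error(self, heavy_current_smoker):
        incomplete = replace(heavy_current_smoker, bmi=None)
        with pytest.raises(IncompleteCovariateError, match="bmi"):
            predict("plcom2012", incomplete, 6)

    def test_module_level_wrappers_match_registry(self, moderate_former_smoker):
        s = moderate_former_smoker
        assert bach_risk(s, 6) == predict("bach", s, 6).probability
        assert knoke_risk(s, 6) == predict("knoke", s, 6).probability
        assert llp_risk(s) == get_model("llp").predict(s, 5).probability


def _random_profiles(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        age = rng.uniform(50, 80)
        current = rng.random() < 0.4
        ysq = 0.0 if current else rng.uniform(1, 25)
        start = rng.uniform(12, 25)
        duration = max(age - start - ysq, 3.0)
        out.append(Subject(
            id=f"r{i}", age=age,
            gender=rng.choice(["male", "female"]),
            race=rng.choice(["white", "black", "hispanic", "asian"]),
            education=int(rng.integers(1, 7)),
            bmi=rng.uniform(18, 40),
            copd=bool(rng.random() < 0.2), emphysema=bool(rng.random() < 0.1),
            personal_history_cancer=bool(rng.random() < 0.05),
            family_history_lc=bool(rng.random() < 0.2),
            history_pneumonia=bool(rng.random() < 0.2), asbestos=False,
            smoking=SmokingHistory(
                status="current" if current else "former",
                duration=duration, intensity=rng.uniform(3, 60),
                years_since_quit=ysq,
            ),
        ))
    return out


PROFILES = _random_profiles(12, seed=20240917)


class TestSharedProperties:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_probabilities_within_unit_interval(self, model_id):
        df = cohort_frame(PROFILES)
        p = get_model(model_id).risk_vector(df, 6.0)
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_monotone_in_smoking_exposure(self, model_id):
        """Risk never decreases with longer duration or higher intensity,
        and never increases with longer cessation, all else fixed."""
        model = get_model(model_id)
        tol = 1e-12
        for s in PROFILES[:8]:
            base = model.predict(s, 6).probability
            longer = replace(
                s, smoking=replace(s.smoking, duration=s.smoking.duration + 4)
            )
            if longer.smoking.duration + (longer.smoking.years_since_quit or 0) < longer.age:
                assert model.predict(longer, 6).probability >= base - tol
            heavier = replace(
                s, smoking=replace(s.smoking, intensity=s.smoking.intensity + 10)
            )
            assert model.predict(heavier, 6).probability >= base - tol
            if s.smoking.status != "former":
                continue
            if model_id.startswith("tsce"):
                # Mechanistic exposure-history models do not admit an
                # "all-else-fixed" quit-time shift (it would slide the whole
                # exposure window earlier in life). The physical quitting
                # counterfactual holds the start age fixed: quitting 5 years
                # earlier (shorter duration, longer cessation) lowers risk.
                if s.smoking.duration > 8:
                    quit_earlier = replace(
                        s, smoking=replace(
                            s.smoking,
                            duration=s.smoking.duration - 5,
                            years_since_quit=s.smoking.years_since_quit + 5,
                        )
                    )
                    assert model.predict(quit_earlier, 6).probability <= base + tol
            elif s.smoking.years_since_quit + 5 + s.smoking.duration < s.age:
                later = replace(
                    s, smoking=replace(s.smoking,
                                       years_since_quit=s.smoking.years_since_quit + 5)
                )
                assert model.predict(later, 6).probability <= base + tol

    @pytest.mark.parametrize("model_id", ITERATIVE_MODELS)
    def test_horizon_consistency_for_iterative_models(self, model_id):
        model = get_model(model_id)
        for s in PROFILES[:6]:
            r1 = model.predict(s, 1).probability
            r5 = model.predict(s, 5).probability
            r6 = model.predict(s, 6).probability
            assert r6 >= r5 >= r1 >= 0

    def test_cross_model_spread(self, heavy_current_smoker):
        """Different models give different absolute risks for the same
        person (no two registered models are numerically identical)."""
        risks = {m: predict(m, heavy_current_smoker, 6).probability for m in MODEL_IDS}
        assert len({round(v, 10) for v in risks.values()}) == len(MODEL_IDS)
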