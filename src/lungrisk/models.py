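"""Absolute-risk calculators behind a single registry interface.

Four model families are implemented, matching the structures of the
published lung cancer risk models they represent:

* ``LogisticRiskModel`` — a logistic form ``inverse-logit(intercept + sum of
  coefficient x centered/transformed covariate)`` giving an absolute risk
  over the model's native time frame (the PLCOm2012 family).
* ``LLPModel`` — multiplies covariate odds ratios into an age-sex baseline
  absolute risk (the Liverpool Lung Project combination rule; 5-year risk).
* ``AnnualCycleModel`` — composes an annual lung-cancer hazard and an
  optional annual competing-death hazard over one-year cycles, advancing
  age, smoking duration (current smokers) and quit-years (former smokers)
  each cycle (the Bach and Knoke structures):
  ``risk = sum_k S_lc(k) S_death(k) p_lc(k)``.
* ``TSCEModel`` — the two-stage clonal expansion hazard of :mod:`.tsce`
  with gender-specific rate parameters and a smoking dose response.

Fixed-time-frame models (PLCOm2012 family: 6 y; LLP family: 5 y) return
their native-horizon risk unchanged when asked for a 5- or 6-year score:
they are used as risk scores against either outcome horizon without
rescaling. Iterative models honor the requested horizon exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Subject, cohort_frame
from .registry import ModelSpec, MODEL_IDS, get_model
from . import tsce as _tsce

__all__ = [
    "RiskPrediction",
    "IncompleteCovariateError",
    "CovariateDomainError",
    "predict",
    "predict_cohort",
    "plcom2012_logit",
    "bach_risk",
    "llp_risk",
    "knoke_risk",
    "LogisticRiskModel",
    "LLPModel",
    "AnnualCycleModel",
    "TSCEModel",
]


@dataclass(frozen=True)
class RiskPrediction:
    id: str
    model_id: str
    outcome: str
    horizon: float
    probability: float


class IncompleteCovariateError(ValueError):
    """A covariate required by the model is missing (impute first)."""

    def __init__(self, field: str, n_missing: int = 1):
        self.field = field
        self.n_missing = n_missing
        super().__init__(f"incomplete covariate {field!r} ({n_missing} missing value(s))")


class CovariateDomainError(ValueError):
    """A covariate value lies outside a transform's domain (e.g. intensity 0
    for a reciprocal-power transform)."""


# ---------------------------------------------------------------------------
# Shared linear-predictor term engine
# ---------------------------------------------------------------------------

_NUMERIC_CASTS = ("age", "education", "bmi", "smoking_duration",
                  "smoking_intensity", "years_since_quit", "pack_years")


def _column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise IncompleteCovariateError(name, len(df))
    col = df[name]
    if name in _NUMERIC_CASTS:
        values = pd.to_numeric(col).to_numpy(dtype=float)
        n_missing = int(np.isnan(values).sum())
    else:
        n_missing = int(col.isna().sum())
        values = col.to_numpy()
    if n_missing:
        raise IncompleteCovariateError(name, n_missing)
    return values


def _eval_term(df: pd.DataFrame, name: str, cfg: dict) -> np.ndarray:
    kind = cfg["type"]
    if kind == "category":
        values = _column(df, name)
        coefs = cfg["coefs"]
        try:
            return np.array([float(coefs[v]) for v in values])
        except KeyError as exc:
            raise CovariateDomainError(f"{name}: unknown category {exc.args[0]!r}") from None
    x = _column(df, name).astype(float)
    coef = float(cfg["coef"])
    if kind == "linear":
        return coef * (x - float(cfg.get("center", 0.0)))
    if kind == "indicator":
        return coef * x.astype(bool).astype(float)
    if kind == "power":
        scale = float(cfg.get("scale", 1.0))
        power = float(cfg["power"])
        if power < 0 and np.any(x <= 0):
            raise CovariateDomainError(
                f"{name}: value <= 0 outside domain of power {power} transform"
            )
        return coef * ((x / scale) ** power - float(cfg.get("center", 0.0)))
    if kind == "log":
        shift = float(cfg.get("shift", 0.0))
        scale = float(cfg.get("scale", 1.0))
        if np.any(x + shift <= 0):
            raise CovariateDomainError(f"{name}: value outside domain of log transform")
        return coef * np.log((x + shift) / scale)
    if kind == "capped_linear":
        return coef * np.minimum(x, float(cfg["cap"]))
    raise ValueError(f"unknown term type {kind!r}")


def _linear_predictor(df: pd.DataFrame, intercept: float, terms: dict) -> np.ndarray:
    lp = np.full(len(df), float(intercept))
    for name, cfg in terms.items():
        lp = lp + _eval_term(df, name, cfg)
    return lp


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _fill_current_ysq(df: pd.DataFrame) -> pd.DataFrame:
    """Current smokers carry a structural zero for years-since-quit; accept
    cohorts that leave the cell blank for them."""
    if "years_since_quit" not in df.columns or "smoking_status" not in df.columns:
        return df
    ysq = pd.to_numeric(df["years_since_quit"])
    blank_current = ysq.isna() & (df["smoking_status"] == "current")
    if blank_current.any():
        df = df.copy()
        df.loc[blank_current, "years_since_quit"] = 0.0
    return df


class _BaseModel:
    native_horizon: float

    def __init__(self, payload: dict, checksum: str):
        self.payload = payload
        self.checksum = checksum
        self.model_id = payload["model_id"]
        self.outcome = payload["outcome"]
        self.native_horizon = float(payload.get("horizon", 6))
        self.spec = ModelSpec(
            model_id=self.model_id,
            outcome=self.outcome,
            horizon=self.native_horizon,
            covariates=tuple(payload.get("covariates", ())),
            checksum=checksum,
        )

    def _prepare(self, df: pd.DataFrame) -> pd.DataFrame:
        df = _fill_current_ysq(df)
        if self.payload.get("force_asbestos_false", False) and "asbestos" in df.columns:
            df = df.copy()
            df["asbestos"] = False
        return df

    def risk_vector(self, df: pd.DataFrame, horizon: float = 6.0) -> np.ndarray:
        raise NotImplementedError

    def predict(self, subject: Subject, horizon: float = 6.0) -> RiskPrediction:
        df = cohort_frame([subject])
        p = float(self.risk_vector(df, horizon)[0])
        return RiskPrediction(
            id=subject.id,
            model_id=self.model_id,
            outcome=self.outcome,
            horizon=horizon,
            probability=p,
        )


class LogisticRiskModel(_BaseModel):
    """Logistic absolute-risk form over a fixed time frame."""

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        df = self._prepare(df)
        return _linear_predictor(df, self.payload["intercept"], self.payload["terms"])

    def risk_vector(self, df, horizon=6.0):
        return _expit(self.linear_predictor(df))


class LLPModel(_BaseModel):
    """Odds-ratio-times-baseline combination: the subject's covariate odds
    ratios multiply the age-sex baseline absolute 5-year risk on the odds
    scale. Family-history age of onset defaults to "late" (>60 y), the
    assumption used when trial data carry only a yes/no flag."""

    def __init__(self, payload, checksum):
        super().__init__(payload, checksum)
        self.family_history_onset = payload.get("family_history_onset", "late")

    def _baseline(self, df: pd.DataFrame) -> np.ndarray:
        table = self.payload["baseline_risk"]
        bands = np.asarray(table["age_bands"], dtype=float)
        age = _column(df, "age").astype(float)
        gender = _column(df, "gender")
        idx = np.clip(np.searchsorted(bands, age, side="right") - 1, 0, len(bands) - 1)
        male = np.asarray(table["male"], dtype=float)
        female = np.asarray(table["female"], dtype=float)
        is_male = np.array([g == "male" for g in gender])
        if not np.all(np.isin(gender, ("male", "female"))):
            raise CovariateDomainError("gender: unknown category")
        return np.where(is_male, male[idx], female[idx])

    def _or_product(self, df: pd.DataFrame) -> np.ndarray:
        ors = self.payload["odds_ratios"]
        product = np.ones(len(df))
        dur_cfg = ors["smoking_duration"]
        breaks = np.asarray(dur_cfg["breaks"], dtype=float)
        dur_ors = np.asarray(dur_cfg["ors"], dtype=float)
        duration = _column(df, "smoking_duration").astype(float)
        idx = np.searchsorted(breaks, duration, side="left")
        product *= dur_ors[np.clip(idx, 0, len(dur_ors) - 1)]
        for field in ("history_pneumonia", "asbestos", "personal_history_cancer"):
            if field in ors:
                flag = _column(df, field).astype(bool)
                product *= np.where(flag, float(ors[field]), 1.0)
        fh_key = f"family_history_lc_{self.family_history_onset}"
        if fh_key in ors:
            flag = _column(df, "family_history_lc").astype(bool)
            product *= np.where(flag, float(ors[fh_key]), 1.0)
        return product

    def risk_vector(self, df, horizon=6.0):
        df = self._prepare(df)
        base = self._baseline(df)
        odds = base / (1.0 - base) * self._or_product(df)
        return odds / (1.0 + odds)


class AnnualCycleModel(_BaseModel):
    """Iterative one-year composition of a lung-cancer hazard and an
    optional competing-death hazard.

    Within each of the ``horizon`` cycles, age advances by one year, smoking
    duration advances for current smokers, and quit-years advance for former
    smokers (integer-year steps; fractional ages are truncated to completed
    years). With competing-death hazard d_k and cancer probability p_k,

        risk = sum_k S_lc(k) S_death(k) p_k,
        S_lc(k) = prod_{j<k} (1 - p_j),   S_death(k) = prod_{j<k} (1 - d_j).
    """

    def _annual_prob(self, df: pd.DataFrame, which: str) -> np.ndarray:
        cfg = self.payload.get(which)
        if cfg is None:
            return np.zeros(len(df))
        lp = _linear_predictor(df, cfg["intercept"], cfg["terms"])
        return 1.0 - np.exp(-np.exp(lp))

    def risk_vector(self, df, horizon=6.0):
        df = self._prepare(df).copy()
        for col in ("age", "smoking_duration", "years_since_quit"):
            if col in df.columns:
                df[col] = np.floor(pd.to_numeric(df[col]).to_numpy(dtype=float))
        status = _column(df, "smoking_status")
        is_current = np.array([s == "current" for s in status])
        n = len(df)
        risk = np.zeros(n)
        s_lc = np.ones(n)
        s_death = np.ones(n)
        cycles = int(round(horizon))
        for _k in range(cycles):
            p_lc = self._annual_prob(df, "lung_cancer_hazard")
            p_death = self._annual_prob(df, "competing_death_hazard")
            risk += s_lc * s_death * p_lc
            s_lc *= 1.0 - p_lc
            s_death *= 1.0 - p_death
            df["age"] = df["age"] + 1.0
            df["smoking_duration"] = df["smoking_duration"] + is_current.astype(float)
            df["years_since_quit"] = df["years_since_quit"] + (~is_current).astype(float)
        return risk


class TSCEModel(_BaseModel):
    """Two-stage clonal expansion risk with gender-specific published-style
    parameter sets; smoking enters through the exposure schedule built from
    the questionnaire history."""

    def __init__(self, payload, checksum):
        super().__init__(payload, checksum)
        dr = payload.get("dose_response", {})
        self.dose_response = _tsce.DoseResponse(**dr)
        self._params = {
            gender: _tsce.TSCEParameters(
                nu=float(p["nu"]),
                alpha=float(p["alpha"]),
                beta=float(p["beta"]),
                mu=float(p["mu"]),
                lag=float(payload.get("lag", 0.0)),
                dose_response=self.dose_response,
                gender=gender,
            )
            for gender, p in payload["parameters"].items()
        }

    def parameters_for(self, gender: str) -> _tsce.TSCEParameters:
        try:
            return self._params[gender]
        except KeyError:
            raise CovariateDomainError(f"gender: no TSCE parameter set for {gender!r}") from None

    def risk_vector(self, df, horizon=6.0):
        df = self._prepare(df)
        age = _column(df, "age").astype(float)
        gender = _column(df, "gender")
        status = _column(df, "smoking_status")
        duration = _column(df, "smoking_duration").astype(float)
        intensity = _column(df, "smoking_intensity").astype(float)
        ysq_raw = _column(df, "years_since_quit").astype(float)
        ysq = np.where(np.array([s == "current" for s in status]), 0.0, ysq_raw)
        start = age - duration - ysq
        if np.any(start < -1e-9):
            bad = int(np.sum(start < -1e-9))
            raise CovariateDomainError(
                f"smoking history implies negative start age for {bad} subject(s)"
            )
        start = np.maximum(start, 0.0)
        quit_age = start + duration
        # three contiguous segments: [0, start) dose 0, [start, quit) dose,
        # [quit, inf) dose 0 (current smokers: quit bound pushed past ages)
        far = age.max() + float(horizon) + 1.0
        is_current = np.array([s == "current" for s in status])
        quit_bound = np.where(is_current, far, quit_age)
        bounds = np.column_stack([np.zeros_like(age), start, quit_bound,
                                  np.full_like(age, far)])
        doses = np.column_stack([np.zeros_like(age), intensity, np.zeros_like(age)])
        risks = np.empty(len(df))
        for g, params in self._params.items():
            mask = np.array([x == g for x in gender])
            if not mask.any():
                continue
            s_now = _tsce.survival_batch(params, bounds[mask], doses[mask], age[mask])
            s_end = _tsce.survival_batch(
                params, bounds[mask], doses[mask], age[mask] + float(horizon)
            )
            risks[mask] = 1.0 - s_end / s_now
        unknown = ~np.isin(gender, list(self._params))
        if unknown.any():
            raise CovariateDomainError("gender: no TSCE parameter set for some subjects")
        return risks


# ---------------------------------------------------------------------------
# Top-level operations
# ---------------------------------------------------------------------------

def predict(model_id: str, subject: Subject, horizon: float = 6.0) -> RiskPrediction:
    """Absolute-risk prediction for one subject under one registered model.

    Deterministic; raises :class:`IncompleteCovariateError` when any of the
    model's covariates is missing (impute first), and a registry error for
    unknown model ids.
    """
    return get_model(model_id).predict(subject, horizon)


def predict_cohort(
    model_ids: Sequence[str],
    df: pd.DataFrame,
    horizon: float = 6.0,
) -> pd.DataFrame:
    """Predictions for a complete cohort frame under several models; returns
    a tidy frame (id, model_id, outcome, horizon, probability)."""
    frames = []
    for mid in model_ids:
        model = get_model(mid)
        probs = model.risk_vector(df, horizon)
        frames.append(
            pd.DataFrame(
                {
                    "id": df["id"].to_numpy(),
                    "model_id": mid,
                    "outcome": model.outcome,
                    "horizon": horizon,
                    "probability": probs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plcom2012_logit(subject: Subject) -> float:
    """Linear predictor (log-odds of 6-y lung cancer incidence) of the
    PLCOm2012 logistic model."""
    model = get_model("plcom2012")
    return float(model.linear_predictor(cohort_frame([subject]))[0])


def bach_risk(subject: Subject, horizon: float = 6.0) -> float:
    """Bach-structure absolute risk: annual lung-cancer and competing-death
    hazards composed over one-year cycles."""
    return get_model("bach").predict(subject, horizon).probability


def llp_risk(subject: Subject) -> float:
    """LLP-structure 5-year absolute lung cancer risk."""
    model = get_model("llp")
    return model.predict(subject, model.native_horizon).probability


def knoke_risk(subject: Subject, horizon: float = 6.0) -> float:
    """Knoke-structure probability of lung cancer death within ``horizon``
    years (annual hazards, no competing-mortality adjustment)."""
    return get_model("knoke").predict(subject, horizon).probability
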