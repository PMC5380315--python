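"""Calibration, discrimination, classification and threshold-matching
metrics for externally validating absolute-risk models on binary outcomes.

Conventions (declared once, used throughout):

* calibration slope — coefficient of logit(prediction) in a logistic
  regression of the outcome on logit(prediction); 1 is ideal, <1 means
  predictions are over-dispersed.
* calibration-in-the-large intercept — intercept of a logistic regression
  with logit(prediction) as a fixed-coefficient-1 offset; 0 is ideal.
* AUC — concordance probability with ties counted 1/2; 95% CI by DeLong.
* sensitivity/specificity — 95% Wilson score intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CalibrationGroup",
    "CalibrationResult",
    "AUCResult",
    "ClassificationResult",
    "MatchedThreshold",
    "calibration_groups",
    "calibration_intercept_slope",
    "auc",
    "delong_variance",
    "sens_spec",
    "match_threshold_to_count",
]


@dataclass(frozen=True)
class CalibrationGroup:
    mean_predicted: float
    observed_proportion: float
    n: int


@dataclass(frozen=True)
class CalibrationResult:
    groups: tuple[CalibrationGroup, ...]
    intercept: float
    slope: float
    intercept_joint: float  # intercept of the two-parameter fit
    separation_flag: bool = False


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class ClassificationResult:
    threshold: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity_ci: Optional[tuple[float, float]]


@dataclass(frozen=True)
class MatchedThreshold:
    threshold: float
    n_target: int
    realized_count: int
    tied: bool


def _check_predictions(predictions) -> np.ndarray:
    p = np.asarray(predictions, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    return p


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def calibration_groups(
    predictions: Sequence[float],
    outcomes: Sequence[bool],
    n_groups: int = 10,
) -> tuple[CalibrationGroup, ...]:
    """Quantile-based risk groups with per-group mean predicted risk and
    observed event proportion (the points of a calibration plot).

    When there are fewer distinct predictions than requested groups, the
    number of groups is reduced with a warning.
    """
    p = _check_predictions(predictions)
    y = np.asarray(outcomes, dtype=bool)
    if len(p) != len(y):
        raise ValueError("predictions and outcomes must have equal length")
    n_distinct = len(np.unique(p))
    if n_groups > n_distinct:
        warnings.warn(
            f"n_groups={n_groups} exceeds {n_distinct} distinct predictions; reducing",
            stacklevel=2,
        )
        n_groups = n_distinct
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_groups + 1)))
    if len(edges) == 1:  # all predictions identical: one group
        return (CalibrationGroup(float(p.mean()), float(y.mean()), len(p)),)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    groups = []
    for g in range(len(edges) - 1):
        mask = idx == g
        if not mask.any():
            continue
        groups.append(
            CalibrationGroup(
                mean_predicted=float(p[mask].mean()),
                observed_proportion=float(y[mask].mean()),
                n=int(mask.sum()),
            )
        )
    assert sum(g.n for g in groups) == len(p)
    return tuple(groups)


def calibration_intercept_slope(
    predictions: Sequence[float],
    outcomes: Sequence[bool],
) -> tuple[float, float, float, bool]:
    """(intercept, slope, intercept_joint, separation_flag).

    ``slope`` is the coefficient of logit(prediction) in a logistic fit of
    the outcome on logit(prediction); ``intercept`` is calibration-in-the-
    large (offset fit with slope fixed at 1); ``intercept_joint`` is the
    free intercept of the two-parameter fit. Perfect separation is flagged
    and the affected estimates reported as unbounded (+/- inf).
    """
    p = _check_predictions(predictions)
    y = np.asarray(outcomes, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    lp = _logit(p)
    exog = sm.add_constant(lp)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=200)
        intercept_joint, slope = float(fit.params[0]), float(fit.params[1])
        if (not np.all(np.isfinite(fit.bse)) or np.abs(slope) > 50
                or np.max(fit.bse) > 100):
            separation = True
    except Exception:
        separation = True
        intercept_joint, slope = np.inf, np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.GLM(
                y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
            ).fit(maxiter=200)
        intercept = float(fit0.params[0])
    except Exception:
        separation = True
        intercept = np.inf
    return intercept, slope, intercept_joint, separation


def calibration(
    predictions: Sequence[float],
    outcomes: Sequence[bool],
    n_groups: int = 10,
) -> CalibrationResult:
    """Grouped calibration plot data plus intercept/slope summaries."""
    groups = calibration_groups(predictions, outcomes, n_groups)
    intercept, slope, intercept_joint, flag = calibration_intercept_slope(
        predictions, outcomes
    )
    return CalibrationResult(groups, intercept, slope, intercept_joint, flag)


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    xs = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and xs[j] == xs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, variance of AUC) by the DeLong structural-components method."""
    cases = scores[labels]
    controls = scores[~labels]
    m, n = len(cases), len(controls)
    all_ranks = _midranks(np.concatenate([cases, controls]))
    case_ranks = _midranks(cases)
    control_ranks = _midranks(controls)
    auc_val = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - case_ranks) / n  # per-case structural components
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc_val), float(s10 / m + s01 / n)


def auc(scores: Sequence[float], outcomes: Sequence[bool]) -> AUCResult:
    """Concordance probability (ties 1/2) with a DeLong 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and outcomes must have equal length")
    if y.all() or not y.any():
        raise ValueError("undefined AUC: one outcome class absent")
    auc_val, var = delong_variance(s, y)
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(0.975)
    return AUCResult(
        auc=auc_val,
        ci_lower=float(np.clip(auc_val - z * se, 0.0, 1.0)),
        ci_upper=float(np.clip(auc_val + z * se, 0.0, 1.0)),
        n_cases=int(y.sum()),
        n_controls=int((~y).sum()),
    )


def sens_spec(
    eligible_flags: Sequence[bool],
    outcomes: Sequence[bool],
    threshold: Optional[float] = None,
) -> ClassificationResult:
    """Sensitivity and specificity of a screening-eligibility rule against a
    binary outcome, with Wilson 95% intervals. Metrics whose denominator is
    empty are reported as None (flagged undefined)."""
    e = np.asarray(eligible_flags, dtype=bool)
    y = np.asarray(outcomes, dtype=bool)
    if len(e) != len(y):
        raise ValueError("flags and outcomes must have equal length")
    tp = int((e & y).sum())
    fp = int((e & ~y).sum())
    fn = int((~e & y).sum())
    tn = int((~e & ~y).sum())

    def _rate_ci(k: int, n: int):
        if n == 0:
            return None, None
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        return k / n, (float(lo), float(hi))

    sens, sens_ci = _rate_ci(tp, tp + fn)
    spec, spec_ci = _rate_ci(tn, tn + fp)
    return ClassificationResult(
        threshold=threshold,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci,
    )


def match_threshold_to_count(
    predictions: Sequence[float], n_target: int
) -> MatchedThreshold:
    """Risk threshold at which a model selects (about) ``n_target`` people:
    the n_target-th largest prediction. With ties at the threshold, all tied
    individuals are included and the realized count is reported alongside."""
    p = np.asarray(predictions, dtype=float)
    if not 0 < n_target <= len(p):
        raise ValueError(f"n_target {n_target} outside 1..{len(p)}")
    threshold = float(np.sort(p)[::-1][n_target - 1])
    realized = int((p >= threshold).sum())
    if realized > n_target:
        warnings.warn(
            f"ties at threshold {threshold}: realized count {realized} > target {n_target}",
            stacklevel=2,
        )
    return MatchedThreshold(
        threshold=threshold,
        n_target=int(n_target),
        realized_count=realized,
        tied=realized > n_target,
    )
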