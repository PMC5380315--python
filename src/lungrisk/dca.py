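"""Decision-curve analysis: net benefit of risk-based screening eligibility
against criteria-based strategies.

At a risk threshold t, classifying someone as screening-eligible is worth
one true positive, while an unnecessary screen costs the threshold odds
t/(1-t) of a true positive:

    net benefit = (TP - FP * t/(1-t)) / n.

Two reciprocal framings of the same weight are exposed to prevent
confusion: ``threshold_odds`` (the weighting factor t/(1-t) in the formula)
and ``harm_ratio`` ((1-t)/t — how much worse missing one detectable cancer
is valued than unnecessarily screening one person).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NetBenefitPoint",
    "ThresholdRange",
    "threshold_odds",
    "harm_ratio",
    "net_benefit",
    "decision_curve",
    "positive_nb_range",
    "interpret_nb_delta",
    "DEFAULT_GRID",
]

#: Default threshold grid: 0.1%-20% in 0.1% steps.
DEFAULT_GRID = np.round(np.arange(0.001, 0.2005, 0.001), 10)


@dataclass(frozen=True)
class NetBenefitPoint:
    threshold: float
    strategy: str
    tp: int
    fp: int
    n: int
    net_benefit: float


@dataclass(frozen=True)
class ThresholdRange:
    model: str
    comparator: str
    lower: Optional[float]  # smallest threshold with positive NB difference
    upper: Optional[float]  # largest
    grid_resolution: float

    @property
    def empty(self) -> bool:
        return self.lower is None


def _check_threshold(t: float) -> float:
    t = float(t)
    if not 0.0 < t < 1.0:
        raise ValueError(f"risk threshold {t} outside (0, 1)")
    return t


def threshold_odds(t: float) -> float:
    """Weighting factor t/(1-t) applied to false positives."""
    t = _check_threshold(t)
    return t / (1.0 - t)


def harm_ratio(t: float) -> float:
    """(1-t)/t: the relative valuation of a missed detectable cancer versus
    one unnecessary screen implied by threshold t (reported to one decimal
    in published threshold tables)."""
    return 1.0 / threshold_odds(t)


def net_benefit(
    eligible_flags: Sequence[bool],
    outcomes: Sequence[bool],
    t: float,
    strategy: str = "strategy",
) -> NetBenefitPoint:
    """Net benefit of one eligibility strategy at threshold t.

    The strategy may be a model at threshold (flags = prediction >= t) or an
    external criteria flag (e.g. pack-year eligibility).
    """
    t = _check_threshold(t)
    e = np.asarray(eligible_flags, dtype=bool)
    y = np.asarray(outcomes, dtype=bool)
    if len(e) == 0:
        raise ValueError("empty cohort")
    if len(e) != len(y):
        raise ValueError("flags and outcomes must have equal length")
    tp = int((e & y).sum())
    fp = int((e & ~y).sum())
    nb = (tp - fp * threshold_odds(t)) / len(e)
    return NetBenefitPoint(t, strategy, tp, fp, len(e), float(nb))


def decision_curve(
    predictions: Sequence[float],
    outcomes: Sequence[bool],
    comparator_flags: Optional[Sequence[bool]] = None,
    grid: Sequence[float] = DEFAULT_GRID,
) -> list[NetBenefitPoint]:
    """Net benefit over a grid of thresholds for four strategies: the model
    (eligibility re-evaluated as prediction >= t at each threshold), the
    fixed comparator criteria (if given), screen-all and screen-none."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid thresholds must lie in (0, 1)")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be sorted and strictly increasing")
    points: list[NetBenefitPoint] = []
    all_flags = np.ones(len(y), dtype=bool)
    none_flags = np.zeros(len(y), dtype=bool)
    for t in grid:
        points.append(net_benefit(p >= t, y, t, "model"))
        if comparator_flags is not None:
            points.append(net_benefit(comparator_flags, y, t, "comparator"))
        points.append(net_benefit(all_flags, y, t, "screen_all"))
        points.append(net_benefit(none_flags, y, t, "screen_none"))
    return points


def positive_nb_range(
    predictions: Sequence[float],
    outcomes: Sequence[bool],
    comparator_flags: Sequence[bool],
    grid: Sequence[float] = DEFAULT_GRID,
    model: str = "model",
    comparator: str = "comparator",
) -> ThresholdRange:
    """First and last grid thresholds at which the model's net benefit
    STRICTLY exceeds the comparator's (empty when it never does)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    positive = []
    for t in grid:
        nb_model = net_benefit(p >= t, y, t, model).net_benefit
        nb_comp = net_benefit(comparator_flags, y, t, comparator).net_benefit
        if nb_model > nb_comp:
            positive.append(t)
    res = float(np.min(np.diff(grid))) if len(grid) > 1 else float("nan")
    if not positive:
        return ThresholdRange(model, comparator, None, None, res)
    return ThresholdRange(model, comparator, float(positive[0]), float(positive[-1]), res)


def interpret_nb_delta(delta_nb: float, t: float) -> tuple[float, float]:
    """Interpret a net-benefit difference at threshold t per 1,000 people
    assessed: (net true positives gained, net false positives avoided).

    A difference of delta corresponds to delta x 1000 extra true positives,
    or, at fixed true positives, delta x 1000 / (t/(1-t)) fewer false
    positives.
    """
    odds = threshold_odds(t)
    return float(delta_nb * 1000.0), float(delta_nb * 1000.0 / odds)
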