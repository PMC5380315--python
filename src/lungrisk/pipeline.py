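"""End-to-end validation pipeline and machine-readable report assembly.

One call runs: implausible-value recoding -> never-smoker exclusion ->
(multiple imputation when the cohort has missing cells) -> predictions for
every requested model -> calibration/discrimination/classification metrics
per model and outcome -> decision-curve analysis and count-matched
threshold comparison against the pack-year criteria comparator. Metrics
computed under multiple imputation are pooled by Rubin's rules (AUC on the
logit scale, calibration slope on the raw scale); net-benefit differences
are averaged across imputations before threshold-range detection.

The report is a plain JSON-serializable dict with a provenance block
(config hash, seed, coefficient-file checksums) so every number is
traceable to its inputs; rerunning with the same config and seed gives a
byte-identical report body.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional, Sequence

import numpy as np

from . import dca as _dca
from . import metrics as _metrics
from .cohort import (
    OutcomeRecord,
    Subject,
    cohort_frame,
    exclude_never_smokers,
    nlst_eligible,
    recode_implausible,
)
from .imputation import ImputationConfig, mice, pool_transformed, rubin_pool
from .registry import MODEL_IDS, get_model, payload_checksums

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    models: tuple[str, ...] = MODEL_IDS
    horizon: float = 6.0  # 5 or 6
    seed: int = 0
    imputation: Optional[ImputationConfig] = None  # None: impute only if needed
    dca_grid: tuple[float, ...] = tuple(_dca.DEFAULT_GRID)
    comparator: str = "nlst"
    n_calibration_groups: int = 10

    def __post_init__(self):
        if self.horizon not in (5, 6, 5.0, 6.0):
            raise ValueError("horizon must be 5 or 6")
        unknown = set(self.models) - set(MODEL_IDS)
        if unknown:
            raise ValueError(f"unknown models in config: {sorted(unknown)}")


def _config_hash(config: RunConfig) -> str:
    payload = {
        "models": list(config.models),
        "horizon": config.horizon,
        "seed": config.seed,
        "imputation": None
        if config.imputation is None
        else {
            "m": config.imputation.m,
            "iterations": config.imputation.iterations,
            "seed": config.imputation.seed,
        },
        "dca_grid": [float(t) for t in config.dca_grid],
        "comparator": config.comparator,
        "n_calibration_groups": config.n_calibration_groups,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _comparator_flags(subjects: Sequence[Subject]) -> np.ndarray:
    flags = []
    for s in subjects:
        e = nlst_eligible(s)
        if e is None:
            raise PipelineError(
                f"stage comparator: eligibility indeterminate for {s.id} (impute first)"
            )
        flags.append(e)
    return np.asarray(flags, dtype=bool)


def _outcome_vector(
    subjects: Sequence[Subject], outcomes: Sequence[OutcomeRecord], which: str
) -> np.ndarray:
    by_id = {o.id: o for o in outcomes}
    try:
        recs = [by_id[s.id] for s in subjects]
    except KeyError as exc:
        raise PipelineError(f"stage outcomes: no outcome record for id {exc.args[0]!r}")
    attr = "lc_incidence" if which == "incidence" else "lc_death"
    return np.array([getattr(r, attr) for r in recs], dtype=bool)


def _model_metrics(probs, y, comparator, n_select, grid, n_groups):
    """Metrics for one model x outcome on one completed dataset."""
    clip = np.clip(probs, 1e-12, 1 - 1e-12)
    auc_res = _metrics.auc(probs, y)
    intercept, slope, intercept_joint, sep = _metrics.calibration_intercept_slope(clip, y)
    groups = _metrics.calibration_groups(clip, y, n_groups)
    matched = _metrics.match_threshold_to_count(probs, n_select)
    cls = _metrics.sens_spec(probs >= matched.threshold, y, matched.threshold)
    nb_diff = []
    for t in grid:
        nb_m = _dca.net_benefit(probs >= t, y, t, "model").net_benefit
        nb_c = _dca.net_benefit(comparator, y, t, "comparator").net_benefit
        nb_diff.append(nb_m - nb_c)
    return {
        "auc": auc_res,
        "calibration": (intercept, slope, intercept_joint, sep, groups),
        "matched": (matched, cls),
        "nb_diff": np.asarray(nb_diff),
    }


def run_pipeline(
    subjects: Sequence[Subject],
    outcomes: Sequence[OutcomeRecord],
    config: RunConfig,
) -> dict:
    """Run the full validation pipeline; returns the report dict."""
    try:
        recoded, changelog = recode_implausible(subjects)
        recoded, warnings_ns = exclude_never_smokers(recoded)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage recode: {exc}") from exc
    if not recoded:
        raise PipelineError("stage recode: empty cohort after exclusions")

    frame = cohort_frame(recoded)
    imputable = [c for c in frame.columns if c not in ("id", "age", "pack_years")]
    # Fields never measured in this cohort (all-missing binaries, e.g.
    # pneumonia history) are assumed absent, the convention used when no
    # donor cohort is supplied; donor imputation is available separately
    # through the imputation module.
    assumed_absent = [
        c for c in ("history_pneumonia", "asbestos")
        if c in frame.columns and frame[c].isna().all()
    ]
    if assumed_absent:
        from dataclasses import replace as _replace

        def _fill(s: Subject) -> Subject:
            kw = {c: False for c in assumed_absent}
            return _replace(s, **kw)

        recoded = [_fill(s) for s in recoded]
        frame = cohort_frame(recoded)
    has_missing = frame[imputable].isna().any().any()
    imp_cfg = config.imputation
    if has_missing and imp_cfg is None:
        imp_cfg = ImputationConfig(m=5, iterations=5, seed=config.seed)
    if has_missing or (imp_cfg is not None and imp_cfg.m > 1):
        try:
            completed_sets = mice(recoded, imp_cfg) if has_missing else [list(recoded)]
        except Exception as exc:
            raise PipelineError(f"stage impute: {exc}") from exc
    else:
        completed_sets = [list(recoded)]

    grid = np.asarray(config.dca_grid, dtype=float)
    report_models: dict = {}
    n_select = None
    per_imp_comparator = []
    per_model: dict = {m: {"incidence": [], "death": []} for m in config.models}

    for completed in completed_sets:
        df = cohort_frame(completed)
        try:
            comparator = _comparator_flags(completed)
        except PipelineError:
            raise
        n_select = int(comparator.sum())
        if n_select == 0:
            raise PipelineError("stage comparator: criteria select nobody")
        per_imp_comparator.append(comparator)
        for mid in config.models:
            model = get_model(mid)
            try:
                probs = model.risk_vector(df, config.horizon)
            except Exception as exc:
                raise PipelineError(f"stage predict[{mid}]: {exc}") from exc
            for which in ("incidence", "death"):
                y = _outcome_vector(completed, outcomes, which)
                if y.all() or not y.any():
                    per_model[mid][which].append(None)
                    continue
                per_model[mid][which].append(
                    _model_metrics(probs, y, comparator, n_select, grid,
                                   config.n_calibration_groups)
                )

    m_imp = len(completed_sets)
    for mid in config.models:
        model = get_model(mid)
        out_entry: dict = {"outcome_type": model.outcome,
                           "native_horizon": model.native_horizon}
        for which in ("incidence", "death"):
            runs = per_model[mid][which]
            if any(r is None for r in runs):
                out_entry[which] = {"error": "outcome class absent"}
                continue
            aucs = [r["auc"].auc for r in runs]
            auc_vars = [((r["auc"].ci_upper - r["auc"].ci_lower) / (2 * 1.959964)) ** 2
                        for r in runs]
            slopes = [r["calibration"][1] for r in runs]
            intercepts = [r["calibration"][0] for r in runs]
            sens = [r["matched"][1].sensitivity for r in runs]
            spec = [r["matched"][1].specificity for r in runs]
            nb_mean = np.mean([r["nb_diff"] for r in runs], axis=0)
            positive = grid[nb_mean > 0]
            groups0 = runs[0]["calibration"][4]
            if m_imp >= 2:
                auc_pooled = pool_transformed(aucs, auc_vars, "logit")
                auc_summary = {
                    "estimate": auc_pooled.q_bar,
                    "ci": list(auc_pooled.ci),
                    "pooled": True,
                }
            else:
                a = runs[0]["auc"]
                auc_summary = {
                    "estimate": a.auc,
                    "ci": [a.ci_lower, a.ci_upper],
                    "pooled": False,
                }
            out_entry[which] = {
                "auc": auc_summary,
                "calibration": {
                    "intercept": float(np.mean(intercepts)),
                    "slope": float(np.mean(slopes)),
                    "groups": [
                        {"mean_predicted": g.mean_predicted,
                         "observed_proportion": g.observed_proportion, "n": g.n}
                        for g in groups0
                    ],
                },
                "matched_threshold": {
                    "threshold": float(np.mean([r["matched"][0].threshold for r in runs])),
                    "n_target": n_select,
                    "sensitivity": float(np.mean(sens)),
                    "specificity": float(np.mean(spec)),
                },
                "positive_nb_range": {
                    "lower": float(positive[0]) if len(positive) else None,
                    "upper": float(positive[-1]) if len(positive) else None,
                },
            }
        report_models[mid] = out_entry

    comparator0 = per_imp_comparator[0]
    y_inc = _outcome_vector(completed_sets[0], outcomes, "incidence")
    criteria_cls = _metrics.sens_spec(comparator0, y_inc)
    n = len(completed_sets[0])
    report = {
        "schema_version": "1",
        "n_subjects": n,
        "n_cases_incidence": int(y_inc.sum()),
        "horizon": float(config.horizon),
        "n_imputations": m_imp,
        "comparator": {
            "name": config.comparator,
            "n_selected": int(comparator0.sum()),
            "sensitivity": criteria_cls.sensitivity,
            "specificity": criteria_cls.specificity,
        },
        "models": report_models,
        "recoded_cells": len(changelog),
        "never_smokers_excluded": len(warnings_ns),
        "assumed_absent_fields": assumed_absent,
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "coefficient_checksums": payload_checksums(),
        },
    }
    return report
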