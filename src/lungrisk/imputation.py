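"""Multiple imputation by chained equations over the subject schema, plus
Rubin's-rules pooling of downstream statistics.

Each variable with missing values gets a conditional model given all other
risk factors: logistic for binary variables, multinomial for categorical/
ordinal ones, and normal-theory linear regression with a Bayesian
coefficient draw followed by predictive-mean matching (5 donors) for
continuous ones — the PMM draw keeps imputed values inside the observed,
bounded, often skewed supports. Variables are swept in increasing-
missingness order; quit-years are imputed only for former smokers (current
smokers carry a structural zero, enforced after every draw); imputed values
are clipped to the data-hygiene bounds (BMI 14-60, intensity <=100).

Cross-cohort donor imputation supports the case where a variable was never
measured in the target cohort but is available in a donor cohort: the two
cohorts are stacked with a source indicator, the variable's conditional
model is fitted on donor rows, and draws are taken for target rows inside
the chained-equation sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .cohort import Subject, cohort_frame, subjects_from_frame

__all__ = [
    "ImputationConfig",
    "PooledEstimate",
    "mice",
    "impute_with_donor",
    "rubin_pool",
    "pool_transformed",
]

#: Variables eligible for imputation, with their default conditional model.
DEFAULT_METHODS = {
    "gender": "logistic",
    "race": "multinomial",
    "education": "multinomial",
    "bmi": "pmm",
    "copd": "logistic",
    "emphysema": "logistic",
    "personal_history_cancer": "logistic",
    "family_history_lc": "logistic",
    "history_pneumonia": "logistic",
    "asbestos": "logistic",
    "smoking_status": "logistic",
    "smoking_duration": "pmm",
    "smoking_intensity": "pmm",
    "years_since_quit": "pmm",
}

_BOUNDS = {
    "bmi": (14.0, 60.0),
    "smoking_intensity": (1.0, 100.0),
    "smoking_duration": (1.0, None),
    "years_since_quit": (0.5, None),
}

_BINARY = {"copd", "emphysema", "personal_history_cancer", "family_history_lc",
           "history_pneumonia", "asbestos"}


@dataclass(frozen=True)
class ImputationConfig:
    """m imputations x ``iterations`` chained-equation sweeps each."""

    m: int = 20
    iterations: int = 10
    seed: int = 0
    variable_methods: dict = dc_field(default_factory=dict)
    pmm_donors: int = 5

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2 (between-imputation variance undefined)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def method_for(self, variable: str) -> str:
        return self.variable_methods.get(variable, DEFAULT_METHODS[variable])


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of one statistic across m imputations."""

    q_bar: float
    u_bar: float
    b: float
    t_var: float
    df: float
    ci: tuple[float, float]
    m: int


def rubin_pool(
    estimates: Sequence[float], variances: Sequence[float]
) -> PooledEstimate:
    """Pool per-imputation estimates and within-imputation variances.

    q_bar = mean estimate; u_bar = mean within variance; b = between
    variance (sample variance of estimates); total t = u_bar + (1+1/m) b;
    df = (m-1)(1 + u_bar/((1+1/m)b))^2; 95% CI from the t distribution.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if len(q) != len(u):
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = u_bar + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + u_bar / ((1.0 + 1.0 / m) * b)) ** 2
        crit = float(t_dist.ppf(0.975, df))
    else:
        df = float("inf")
        crit = 1.959963984540054
    half = crit * np.sqrt(t_var)
    return PooledEstimate(q_bar, u_bar, b, float(t_var), float(df),
                          (q_bar - half, q_bar + half), m)


def pool_transformed(
    estimates: Sequence[float],
    variances: Sequence[float],
    transform: str = "logit",
) -> PooledEstimate:
    """Rubin pooling on a transformed scale (delta-method variances), with
    the point estimate and CI mapped back. ``logit`` keeps pooled AUCs and
    proportions inside (0, 1); ``identity`` pools on the raw scale."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if transform == "identity":
        return rubin_pool(q, u)
    if transform != "logit":
        raise ValueError(f"unknown transform {transform!r}")
    ql = logit(q)
    ul = u / (q * (1.0 - q)) ** 2
    pooled = rubin_pool(ql, ul)
    return PooledEstimate(
        q_bar=float(expit(pooled.q_bar)),
        u_bar=pooled.u_bar,
        b=pooled.b,
        t_var=pooled.t_var,
        df=pooled.df,
        ci=(float(expit(pooled.ci[0])), float(expit(pooled.ci[1]))),
        m=pooled.m,
    )


# ---------------------------------------------------------------------------
# Chained equations
# ---------------------------------------------------------------------------

def _encode(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric working matrix: binaries 0/1, gender male=1, status current=1,
    race one-hot (white reference)."""
    out = pd.DataFrame(index=df.index)
    out["age"] = pd.to_numeric(df["age"])
    for col in ("bmi", "smoking_duration", "smoking_intensity", "years_since_quit",
                "education"):
        out[col] = pd.to_numeric(df[col])
    for col in _BINARY:
        out[col] = df[col].map({True: 1.0, False: 0.0})
    out["gender"] = df["gender"].map({"male": 1.0, "female": 0.0})
    out["smoking_status"] = df["smoking_status"].map({"current": 1.0, "former": 0.0})
    for race in ("black", "hispanic", "asian", "pacific_islander", "native_american"):
        out[f"race_{race}"] = np.where(
            df["race"].isna(), np.nan, (df["race"] == race).astype(float)
        )
    return out


_RACES = ("white", "black", "hispanic", "asian", "pacific_islander", "native_american")


def _predictor_columns(target: str, columns: Sequence[str]) -> list[str]:
    own = {target, "race", "race_code"}
    if target == "race":
        own |= {c for c in columns if c.startswith("race_")}
    return [c for c in columns if c not in own]


def _design(X: pd.DataFrame, rows: np.ndarray, cols: list[str]) -> np.ndarray:
    mat = X.loc[rows, cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(mat)), mat])


def _draw_pmm(rng, y_obs, A_obs, A_mis, donors: int) -> np.ndarray:
    """Bayesian linear regression + predictive-mean matching."""
    n, k = A_obs.shape
    beta_hat, *_ = np.linalg.lstsq(A_obs, y_obs, rcond=None)
    resid = y_obs - A_obs @ beta_hat
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_star = sigma2 * dof / max(float(rng.chisquare(dof)), 1e-12)
    xtx = A_obs.T @ A_obs
    try:
        cov = sigma2_star * np.linalg.inv(xtx + 1e-8 * np.eye(k))
        beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    except np.linalg.LinAlgError:
        beta_star = beta_hat
    pred_obs = A_obs @ beta_hat
    pred_mis = A_mis @ beta_star
    order = np.argsort(pred_obs, kind="mergesort")
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    out = np.empty(len(pred_mis))
    for i, (pm, ip) in enumerate(zip(pred_mis, pos)):
        lo = max(ip - donors, 0)
        hi = min(ip + donors, n)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        nearest = window[np.argsort(dist, kind="mergesort")[:donors]]
        out[i] = y_obs[rng.choice(nearest)] if len(nearest) else y_obs[rng.integers(n)]
    return out


def _fit_classifier(A_obs, y_obs, A_mis, rng, variable: str):
    """Class-probability draws for missing rows; returns array of drawn
    labels (float codes). Falls back to a marginal draw on failure."""
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(len(A_mis), classes[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(C=100.0, max_iter=1000)
            clf.fit(A_obs, y_obs)
        proba = clf.predict_proba(A_mis)
    except Exception:
        warnings.warn(f"{variable}: conditional fit failed; marginal draw", stacklevel=2)
        freqs = np.array([(y_obs == c).mean() for c in classes])
        proba = np.tile(freqs, (len(A_mis), 1))
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(A_mis))[:, None]
    idx = (u > cum).sum(axis=1)
    return clf_classes_to_values(classes, idx)


def clf_classes_to_values(classes, idx):
    return np.asarray(classes)[np.clip(idx, 0, len(classes) - 1)]


def _enforce_structure(X: pd.DataFrame) -> None:
    current = X["smoking_status"] == 1.0
    X.loc[current, "years_since_quit"] = 0.0


def _clip_bounds(X: pd.DataFrame, variable: str, rows) -> None:
    lo, hi = _BOUNDS.get(variable, (None, None))
    if lo is not None:
        X.loc[rows, variable] = np.maximum(X.loc[rows, variable], lo)
    if hi is not None:
        X.loc[rows, variable] = np.minimum(X.loc[rows, variable], hi)
    if variable in ("smoking_duration", "years_since_quit"):
        cap = X.loc[rows, "age"] - 1.0
        X.loc[rows, variable] = np.minimum(X.loc[rows, variable], cap)


def _impute_variable(X, variable, miss_rows, fit_rows, method, rng, cfg,
                     exclude=()):
    cols = _predictor_columns(
        variable, [c for c in X.columns if c != "race" and c not in exclude]
    )
    # predictors must be complete on the current working matrix
    A_fit = _design(X, fit_rows, cols)
    A_mis = _design(X, miss_rows, cols)
    y_obs = X.loc[fit_rows, variable].to_numpy(dtype=float)
    if method == "pmm":
        drawn = _draw_pmm(rng, y_obs, A_fit, A_mis, cfg.pmm_donors)
    elif method in ("logistic", "multinomial"):
        drawn = _fit_classifier(A_fit, y_obs, A_mis, rng, variable)
    else:
        raise ValueError(f"unknown method {method!r} for {variable!r}")
    X.loc[miss_rows, variable] = drawn
    _clip_bounds(X, variable, miss_rows)


def _race_to_code(df_race: pd.Series) -> pd.Series:
    return df_race.map({r: i for i, r in enumerate(_RACES)}).astype(float)


def _race_from_code(codes: np.ndarray) -> list[str]:
    return [_RACES[int(c)] for c in codes]


def _run_chain(df, cfg, rng, donor_variable=None, donor_mask=None):
    """One imputation: initialize missing cells from observed marginals and
    sweep conditional draws. Returns the completed encoded matrix."""
    X = _encode(df)
    X["race_code"] = _race_to_code(df["race"])
    miss = {
        v: X[v if v != "race" else "race_code"].isna().to_numpy()
        for v in DEFAULT_METHODS
    }
    if donor_variable is not None:
        X["_donor"] = donor_mask.astype(float)
    to_impute = [v for v, mask in miss.items() if mask.any()]
    for v in to_impute:
        col = "race_code" if v == "race" else v
        observed = X[col].dropna().to_numpy()
        if len(observed) == 0:
            raise ValueError(f"variable {v!r} has no observed values")
        X.loc[miss[v], col] = rng.choice(observed, size=int(miss[v].sum()))
        if v == "race":
            _sync_race_dummies(X)
    _enforce_structure(X)
    order = sorted(to_impute, key=lambda v: miss[v].sum())
    for _it in range(cfg.iterations):
        for v in order:
            rows_mis = np.flatnonzero(miss[v])
            rows_fit = np.flatnonzero(~miss[v])
            exclude = ("_donor",) if donor_variable == v else ()
            if donor_variable == v:
                # fit on donor rows only; the source indicator is constant
                # there and must not enter this variable's design
                rows_fit = np.flatnonzero(~miss[v] & donor_mask)
            if v == "years_since_quit":
                former_fit = rows_fit[X.loc[rows_fit, "smoking_status"] == 0.0]
                former_mis = rows_mis[X.loc[rows_mis, "smoking_status"] == 0.0]
                if len(former_mis) and len(former_fit):
                    _impute_variable(X, v, former_mis, former_fit, cfg.method_for(v),
                                     rng, cfg)
                _enforce_structure(X)
                continue
            if v == "race":
                _impute_race(X, rows_mis, rows_fit, rng)
                continue
            if v == "education":
                _impute_categorical(X, "education", rows_mis, rows_fit, rng,
                                    cfg.method_for(v), cfg)
                continue
            if not len(rows_mis) or not len(rows_fit):
                continue
            _impute_variable(X, v, rows_mis, rows_fit, cfg.method_for(v), rng, cfg,
                             exclude=exclude)
        _enforce_structure(X)
    return X, miss


def _sync_race_dummies(X: pd.DataFrame) -> None:
    for i, race in enumerate(_RACES):
        if race == "white":
            continue
        X[f"race_{race}"] = (X["race_code"] == float(i)).astype(float)


def _impute_race(X, rows_mis, rows_fit, rng):
    if not len(rows_mis) or not len(rows_fit):
        return
    cols = _predictor_columns("race", [c for c in X.columns
                                       if c not in ("race", "race_code")])
    A_fit = _design(X, rows_fit, cols)
    A_mis = _design(X, rows_mis, cols)
    y_obs = X.loc[rows_fit, "race_code"].to_numpy(dtype=float)
    drawn = _fit_classifier(A_fit, y_obs, A_mis, rng, "race")
    X.loc[rows_mis, "race_code"] = drawn
    _sync_race_dummies(X)


def _impute_categorical(X, variable, rows_mis, rows_fit, rng, method, cfg):
    if not len(rows_mis) or not len(rows_fit):
        return
    cols = _predictor_columns(variable, [c for c in X.columns if c != "race"])
    A_fit = _design(X, rows_fit, cols)
    A_mis = _design(X, rows_mis, cols)
    y_obs = X.loc[rows_fit, variable].to_numpy(dtype=float)
    if method == "pmm":
        drawn = np.round(_draw_pmm(rng, y_obs, A_fit, A_mis, cfg.pmm_donors))
    else:
        drawn = _fit_classifier(A_fit, y_obs, A_mis, rng, variable)
    X.loc[rows_mis, variable] = np.clip(drawn, 1, 6)


def _decode(df: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("bmi", "smoking_duration", "smoking_intensity", "years_since_quit"):
        out[col] = X[col].to_numpy()
    out["education"] = X["education"].to_numpy()
    for col in _BINARY:
        out[col] = X[col].to_numpy() == 1.0
    out["gender"] = np.where(X["gender"].to_numpy() == 1.0, "male", "female")
    out["smoking_status"] = np.where(
        X["smoking_status"].to_numpy() == 1.0, "current", "former"
    )
    out["race"] = _race_from_code(X["race_code"].to_numpy())
    out["pack_years"] = pd.to_numeric(df["pack_years"]).fillna(
        pd.Series(
            X["smoking_duration"].to_numpy() * X["smoking_intensity"].to_numpy() / 20.0,
            index=df.index,
        )
    )
    return out


def _restore_observed(df: pd.DataFrame, completed: pd.DataFrame) -> pd.DataFrame:
    """Guarantee observed cells are byte-identical to the input."""
    out = completed.copy()
    for col in df.columns:
        out[col] = df[col].where(df[col].notna(), completed[col])
    return out


def mice(subjects: Sequence[Subject], config: ImputationConfig) -> list[list[Subject]]:
    """m completed copies of the cohort (observed values untouched,
    reproducible under the config seed)."""
    df = cohort_frame(subjects)
    never = df["smoking_status"] == "never"
    if never.any():
        raise ValueError("never-smokers present; exclude before imputation")
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(config.m)
    completed_sets: list[list[Subject]] = []
    any_missing = df[list(DEFAULT_METHODS)].isna().any().any()
    for imp in range(config.m):
        if not any_missing:
            completed_sets.append(subjects_from_frame(df))
            continue
        X, _ = _run_chain(df, config, rngs[imp])
        completed = _restore_observed(df, _decode(df, X))
        completed_sets.append(subjects_from_frame(completed))
    return completed_sets


def impute_with_donor(
    target: Sequence[Subject],
    donor: Sequence[Subject],
    variable: str,
    config: ImputationConfig,
) -> list[list[Subject]]:
    """Impute a variable missing entirely in ``target`` using ``donor``
    rows: cohorts are stacked with a source indicator, the variable's
    conditional model is fitted on donor rows, and target values are drawn
    within the chained-equation sweeps. Returns m completed target cohorts.
    """
    if len(donor) == 0:
        raise ValueError("empty donor cohort")
    if variable not in DEFAULT_METHODS:
        raise ValueError(f"unknown variable {variable!r}")
    df_t = cohort_frame(target)
    df_d = cohort_frame(donor)
    if not df_d[variable].notna().any():
        raise ValueError(f"donor cohort has no observed values for {variable!r}")
    stacked = pd.concat([df_d, df_t], ignore_index=True)
    donor_mask = np.zeros(len(stacked), dtype=bool)
    donor_mask[: len(df_d)] = True
    root = np.random.default_rng(config.seed)
    rngs = root.spawn(config.m)
    out: list[list[Subject]] = []
    for imp in range(config.m):
        X, _ = _run_chain(stacked, config, rngs[imp],
                          donor_variable=variable, donor_mask=donor_mask)
        completed = _restore_observed(stacked, _decode(stacked, X))
        target_part = completed.iloc[len(df_d):].reset_index(drop=True)
        out.append(subjects_from_frame(target_part))
    return out
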