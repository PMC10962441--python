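"""Statistical battery for the longitudinal cohort analysis.

Implements the model families used to relate perivascular-space markers
to small-vessel-disease burden, cognition and incident dementia:

* cross-sectional linear regression with standardized coefficients,
* linear mixed models (random intercept + slope on time, ML fit) with
  empirical-Bayes per-subject slope extraction,
* logistic regression for binary marker change,
* Cox proportional hazards with Efron tie handling and the nested
  covariate sets of the analysis plan,
* Benjamini–Hochberg FDR per results-table family,
* optimal-cutpoint search (Youden's J over observed midpoints) with
  Kaplan–Meier / log-rank survival stratification,
* seeded random-forest permutation variable importance.

Model fitting itself is delegated to statsmodels / lifelines /
scikit-learn; this module owns the design construction (standardization,
covariate sets, smoking dummies), the contracts and the reporting shape.
Standardized coefficients z-score the outcome and continuous predictors;
binary covariates are left untouched.  Mixed models are fitted by ML
(not REML) and their p-values are Wald normal approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelResult",
    "SubjectSlopes",
    "CutpointResult",
    "COVARIATE_SETS",
    "resolve_covariates",
    "fit_linear",
    "fit_lmm",
    "fit_logistic",
    "fit_cox",
    "fdr_adjust",
    "best_cutpoint",
    "km_logrank",
    "variable_importance",
]

#: the vascular risk factors used as covariates throughout
RISK_FACTORS = ("htn", "dm", "chol", "smoking")

#: nested covariate sets of the analysis plan
COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "base": ("age0", "sex") + RISK_FACTORS,
    "base_nart": ("age0", "sex") + RISK_FACTORS + ("nart_iq",),
    "base_nart_csvd": ("age0", "sex")
    + RISK_FACTORS
    + ("nart_iq", "wmh", "lacunes", "microbleeds"),
    "base_nart_md": ("age0", "sex") + RISK_FACTORS + ("nart_iq", "md_median"),
    "base_nart_psmd": ("age0", "sex") + RISK_FACTORS + ("nart_iq", "psmd"),
}

#: default predictor panel for variable importance
IMPORTANCE_PREDICTORS = (
    "age0",
    "sex",
    "nart_iq",
    "wmh",
    "lacunes",
    "microbleeds",
    "alps",
    "pvs_wb",
    "psmd",
    "md_median",
)


def resolve_covariates(covariates: str | tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Accept a covariate-set identifier or an explicit column tuple."""
    if isinstance(covariates, str):
        try:
            return COVARIATE_SETS[covariates]
        except KeyError:
            raise KeyError(
                f"unknown covariate set {covariates!r}; "
                f"known: {sorted(COVARIATE_SETS)}"
            ) from None
    return tuple(covariates)


@dataclass
class ModelSpec:
    """What to fit: outcome, predictor of interest, covariates, family."""

    outcome: str
    predictor: str | None = None
    covariates: str | tuple[str, ...] = ()
    family: str = "linear"  # linear | lmm | logistic | cox
    standardize: bool = True
    label: str | None = None

    def covariate_columns(self) -> tuple[str, ...]:
        return resolve_covariates(self.covariates)


@dataclass
class ModelResult:
    """One fitted coefficient of interest with its uncertainty."""

    estimate: float  # standardized beta, OR, or HR
    ci_low: float
    ci_high: float
    p: float
    n: int
    family: str
    outcome: str
    predictor: str
    converged: bool = True
    p_fdr: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "family": self.family,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "n": self.n,
            "converged": self.converged,
        }


@dataclass
class SubjectSlopes:
    """Per-subject intercepts/slopes extracted from a mixed model."""

    table: pd.DataFrame  # subject_id, intercept, slope
    method: str = "blup"


@dataclass
class CutpointResult:
    cutpoint: float
    direction: str  # "<=" means scores <= cutpoint flag the risk group
    youden: float
    sensitivity: float
    specificity: float


def _is_continuous(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return False
    return series.nunique(dropna=True) > 2


def _zscore(series: pd.Series) -> pd.Series:
    sd = series.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"column {series.name!r} is constant: cannot standardize")
    return (series - series.mean()) / sd


def _prepare(
    table: pd.DataFrame,
    columns: list[str],
    standardize: bool,
    z_columns: set[str],
) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    df = table[columns].dropna().copy()
    if standardize:
        for c in columns:
            if c in z_columns and _is_continuous(df[c]):
                df[c] = _zscore(df[c])
    return df


def _formula_terms(covariates: tuple[str, ...]) -> list[str]:
    return [f"C({c})" if c == "smoking" else c for c in covariates]


def _check_rank(df: pd.DataFrame, cols: list[str]) -> None:
    numeric = df[[c for c in cols if c != "smoking"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(numeric)), numeric])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        base = np.ones((len(numeric), 1))
        for j, c in enumerate([c for c in cols if c != "smoking"]):
            cand = np.column_stack([base, numeric[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(c)
            else:
                base = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_linear(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS of ``spec.outcome`` on ``spec.predictor`` plus covariates.

    With standardization on, the outcome and all continuous predictors
    are z-scored so the reported coefficient is a standardized β.
    Requires ≥10 complete cases; rank-deficient designs raise with the
    collinear columns named.
    """
    if spec.predictor is None:
        raise ValueError("linear model needs a predictor of interest")
    covs = spec.covariate_columns()
    cols = [spec.outcome, spec.predictor, *covs]
    z_cols = {spec.outcome, spec.predictor, *covs}
    df = _prepare(table, cols, spec.standardize, z_cols)
    if len(df) < 10:
        raise ValueError(f"need at least 10 complete cases, got {len(df)}")
    if df[spec.predictor].nunique() < 2:
        raise ValueError(f"predictor {spec.predictor!r} is constant")
    _check_rank(df, [spec.predictor, *covs])
    terms = [spec.predictor, *_formula_terms(covs)]
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    res = smf.ols(formula, data=df).fit()
    ci = res.conf_int().loc[spec.predictor]
    return ModelResult(
        estimate=float(res.params[spec.predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues[spec.predictor]),
        n=int(res.nobs),
        family="linear",
        outcome=spec.outcome,
        predictor=spec.predictor,
        diagnostics={"r2": float(res.rsquared)},
    )


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    time_col: str = "visit_year",
    group_col: str = "subject_id",
) -> tuple[ModelResult, SubjectSlopes]:
    """Linear mixed model with random intercept and slope on time.

    Fitted by maximum likelihood.  Two usages:

    * ``spec.predictor is None`` — the longitudinal-change model: the
      coefficient of interest is the fixed time slope (marker units per
      year).
    * with a predictor — baseline marker as predictor of change: the
      coefficient of interest is the predictor × time interaction.

    Per-subject slopes are extracted as empirical-Bayes (BLUP) sums of
    the fixed and random slope parts.  A singular random-effects
    covariance triggers a recorded fallback to random-intercept-only.
    """
    covs = spec.covariate_columns()
    base_cols = [spec.outcome, time_col, group_col, *covs]
    pred = spec.predictor
    if pred is not None:
        base_cols.insert(2, pred)
    z_cols = {spec.outcome, pred} if spec.standardize else set()
    z_cols.discard(None)
    df = _prepare(table, base_cols, spec.standardize, z_cols | set(covs) - {"smoking", "sex", "htn", "dm", "chol"})

    visits = df.groupby(group_col)[time_col].nunique()
    if (visits >= 2).mean() < 0.5 or visits.max() < 2:
        raise ValueError(
            "slope unidentifiable: fewer than half the subjects have >= 2 visits"
        )

    terms = [time_col]
    if pred is not None:
        terms += [pred, f"{pred}:{time_col}"]
    terms += _formula_terms(covs)
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    interest = f"{pred}:{time_col}" if pred is not None else time_col

    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = None
        model = smf.mixedlm(formula, df, groups=df[group_col], re_formula=f"~{time_col}")
        # Powell handles the near-boundary variance surfaces these data
        # produce far better than the gradient-based default
        for method in ("powell", None):
            try:
                fit = (
                    model.fit(reml=False, method=method, maxiter=2000)
                    if method
                    else model.fit(reml=False)
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            ok = (
                fit.converged
                and np.isfinite(fit.bse[interest])
                and np.all(np.isfinite(fit.cov_re.to_numpy()))
                and np.linalg.det(fit.cov_re) >= 0
            )
            if ok:
                res = fit
                break
            if res is None:
                res = fit  # keep best-effort fit in case all attempts fail
        if res is None or not res.converged:
            # singular random-effects covariance: random-intercept-only
            fallback = True
            model = smf.mixedlm(formula, df, groups=df[group_col], re_formula="~1")
            try:
                res = model.fit(reml=False, method="powell", maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                res = model.fit(reml=False)

    ci = res.conf_int().loc[interest]
    fe = res.fe_params

    # BLUP slope per subject: fixed time part (+ interaction) + random slope
    re = res.random_effects
    slope_rows = []
    for g, sub in df.groupby(group_col):
        slope = float(fe[time_col])
        if pred is not None:
            slope += float(fe[interest]) * float(sub[pred].iloc[0])
        r = re.get(g)
        rand_int = 0.0
        if r is not None:
            rand_int = float(r.iloc[0])
            if time_col in r.index:
                slope += float(r[time_col])
        intercept = float(fe["Intercept"]) + rand_int
        slope_rows.append({group_col: g, "intercept": intercept, "slope": slope})
    slopes = SubjectSlopes(table=pd.DataFrame(slope_rows), method="blup")

    cov_re = res.cov_re.to_numpy()
    diagnostics = {
        "random_intercept_var": float(cov_re[0, 0]),
        "random_slope_var": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        "residual_var": float(res.scale),
        "fallback_random_intercept_only": fallback,
        "p_value_method": "wald_normal",
    }
    result = ModelResult(
        estimate=float(fe[interest]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues[interest]),
        n=int(df[group_col].nunique()),
        family="lmm",
        outcome=spec.outcome,
        predictor=interest,
        converged=bool(res.converged),
        diagnostics=diagnostics,
    )
    return result, slopes


def fit_logistic(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Maximum-likelihood logistic regression; OR for the predictor.

    Complete separation is detected and reported as non-convergent with
    a NaN estimate rather than a silently diverging coefficient.
    """
    if spec.predictor is None:
        raise ValueError("logistic model needs a predictor of interest")
    covs = spec.covariate_columns()
    cols = [spec.outcome, spec.predictor, *covs]
    df = _prepare(table, cols, spec.standardize, {spec.predictor, *covs})
    y = df[spec.outcome]
    if y.nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} has a single class")
    terms = [spec.predictor, *_formula_terms(covs)]
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.logit(formula, data=df).fit(disp=0, maxiter=200)
            separated = not res.mle_retvals.get("converged", False) or np.abs(
                res.params[spec.predictor]
            ) > 50
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = None
            separated = True
    if separated:
        return ModelResult(
            estimate=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p=float("nan"),
            n=len(df),
            family="logistic",
            outcome=spec.outcome,
            predictor=spec.predictor,
            converged=False,
            diagnostics={"separation": True},
        )
    ci = res.conf_int().loc[spec.predictor]
    return ModelResult(
        estimate=float(np.exp(res.params[spec.predictor])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p=float(res.pvalues[spec.predictor]),
        n=int(res.nobs),
        family="logistic",
        outcome=spec.outcome,
        predictor=spec.predictor,
        diagnostics={"log_or": float(res.params[spec.predictor])},
    )


def fit_cox(
    table: pd.DataFrame,
    spec: ModelSpec,
    duration_col: str = "dementia_time",
    event_col: str = "dementia_event",
) -> ModelResult:
    """Cox proportional-hazards fit (Efron ties, via lifelines).

    With standardization on, the HR is per SD of the predictor of
    interest.  Requires ≥5 events and strictly positive times.
    """
    if spec.predictor is None:
        raise ValueError("cox model needs a predictor of interest")
    covs = spec.covariate_columns()
    cols = [duration_col, event_col, spec.predictor, *covs]
    df = _prepare(table, cols, spec.standardize, {spec.predictor, *covs})
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    if n_events < 5:
        raise ValueError(f"need at least 5 events, got {n_events}")
    if (df[duration_col] <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if "smoking" in df.columns:
        df = pd.get_dummies(df, columns=["smoking"], drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        return ModelResult(
            estimate=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p=float("nan"),
            n=len(df),
            family="cox",
            outcome=event_col,
            predictor=spec.predictor,
            converged=False,
            diagnostics={"error": str(exc)},
        )
    row = cph.summary.loc[spec.predictor]
    return ModelResult(
        estimate=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        n=len(df),
        family="cox",
        outcome=event_col,
        predictor=spec.predictor,
        diagnostics={"log_hr": float(row["coef"]), "n_events": n_events},
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up within one family (one results table)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def best_cutpoint(
    scores, events, direction: str | None = None
) -> CutpointResult:
    """Optimal cutpoint maximizing Youden's J over observed midpoints.

    ``direction`` "<=" classifies scores at or below the cutpoint as the
    risk group; ">=" the reverse.  When None, it is inferred from the
    sign of the score–event association (lower mean score among events ⇒
    "<=").  Ties in J are broken toward the cutoff giving the most
    balanced group sizes, then the smaller cutoff.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=int)
    if s.shape != e.shape:
        raise ValueError("scores and events must have equal length")
    if len(np.unique(e)) < 2:
        raise ValueError("both event classes must be present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("scores are constant: no cutpoint exists")
    if direction is None:
        direction = "<=" if s[e == 1].mean() < s[e == 0].mean() else ">="
    if direction not in ("<=", ">="):
        raise ValueError("direction must be '<=' or '>='")

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(e.sum())
    n_neg = int(len(e) - n_pos)
    best = None
    for c in mids:
        flagged = s <= c if direction == "<=" else s >= c
        tp = int(np.sum(flagged & (e == 1)))
        tn = int(np.sum(~flagged & (e == 0)))
        sens = tp / n_pos
        spec_ = tn / n_neg
        j = sens + spec_ - 1.0
        imbalance = abs(int(flagged.sum()) - int((~flagged).sum()))
        key = (-j, imbalance, c)
        if best is None or key < best[0]:
            best = (key, c, j, sens, spec_)
    _, c, j, sens, spec_ = best
    return CutpointResult(
        cutpoint=float(c),
        direction=direction,
        youden=float(j),
        sensitivity=float(sens),
        specificity=float(spec_),
    )


def km_logrank(
    durations, events, groups
) -> dict:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    Returns ``{"curves": {label: DataFrame}, "at_risk": {label: DataFrame},
    "statistic": float, "p": float}``.  With no events anywhere the
    curves are flat at 1 and the test is degenerate (statistic 0, p 1).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {len(labels)}")
    for lab in labels:
        if not np.any(groups == lab):
            raise ValueError(f"group {lab!r} is empty")
    curves: dict = {}
    at_risk: dict = {}
    for lab in labels:
        sel = groups == lab
        kmf = KaplanMeierFitter(label=str(lab))
        kmf.fit(durations[sel], events[sel])
        curves[lab] = kmf.survival_function_
        at_risk[lab] = kmf.event_table
    if events.sum() == 0:
        stat, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(durations, groups, events)
        stat, p = float(res.test_statistic), float(res.p_value)
    return {"curves": curves, "at_risk": at_risk, "statistic": stat, "p": p}


def _oob_permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean OOB squared-error increase under permutation.

    For each tree, predictions on its out-of-bag samples give a baseline
    loss; permuting one feature column within those samples and
    re-predicting gives the permuted loss.  Importance is the mean loss
    increase over trees and repeats — out-of-bag, so a pure-noise
    feature scores near zero instead of its in-sample overfit value.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    increases: list[list[float]] = [[] for _ in range(p)]
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size < 2:
            continue
        Xo = X[oob]
        base = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        for j in range(p):
            for _ in range(n_repeats):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                loss = np.mean((y[oob] - tree.predict(Xp)) ** 2)
                increases[j].append(loss - base)
    mean = np.array([np.mean(v) if v else 0.0 for v in increases])
    sd = np.array([np.std(v) if v else 0.0 for v in increases])
    return mean, sd


def variable_importance(
    table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] | None = None,
    seed: int = 0,
    n_estimators: int = 300,
    n_repeats: int = 2,
) -> pd.DataFrame:
    """Seeded random-forest permutation importance, ranked descending.

    A regression forest is grown on complete cases; importance is the
    mean out-of-bag squared-error increase when a predictor is permuted
    (``n_repeats`` permutations per tree).  The default panel is the
    full marker set used
    for the multicollinearity-robust ranking (age, sex, NART-IQ, WMH,
    lacunes, microbleeds, DTI-ALPS, PVS volume, PSMD, median MD).  This
    is a standard random forest, not a conditional-inference forest;
    correlated predictors share importance (noted in the output attrs).
    """
    if predictors is None:
        predictors = IMPORTANCE_PREDICTORS
    predictors = tuple(predictors)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    cols = [outcome, *predictors]
    df = table[cols].dropna()
    if df.empty:
        raise ValueError("no complete cases after listwise deletion")
    y = df[outcome].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError(f"outcome {outcome!r} is constant")
    X = df[list(predictors)].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    mean, sd = _oob_permutation_importance(
        forest, X, y, n_repeats=n_repeats, seed=seed
    )
    out = pd.DataFrame(
        {
            "predictor": predictors,
            "importance": mean,
            "importance_sd": sd,
        }
    ).sort_values("importance", ascending=False, ignore_index=True)
    out.attrs["method"] = "random_forest_permutation"
    out.attrs["note"] = (
        "standard random forest with permutation importance; correlated "
        "predictors share importance (not a conditional-inference forest)"
    )
    out.attrs["seed"] = seed
    return out
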