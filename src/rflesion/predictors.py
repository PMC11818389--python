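"""Predictor analysis for RF application duration.

Which lesion covariates (mean contact force, starting contact force, LI
drop, LI starting impedance, interlesion distance) drive the RF
application duration under each stopping rule?  Because the durations
are non-Gaussian and a reference linear fit shows heteroscedastic
residuals, the analysis pairs a generalized additive model (one
penalized-spline smooth per predictor, per-term significance) with a
random-forest regression (impurity importances, cross-validated MSE and
R^2).  A low cross-validated R^2 automatically flags the forest
importances as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.diagnostic import het_breuschpagan, normal_ad

__all__ = [
    "DEFAULT_PREDICTORS",
    "DiagnosticsReport",
    "GAMResult",
    "ImportanceReport",
    "distribution_diagnostics",
    "collinearity_diagnostics",
    "heteroscedasticity_lm",
    "fit_duration_gam",
    "rf_importance",
]

#: the five lesion covariates entering the duration regressions
DEFAULT_PREDICTORS = ["cf_mean_g", "cf_start_g", "li_drop_ohm", "li_start_ohm", "ild_mm"]

#: forests with cross-validated R^2 below this are flagged unreliable
RELIABILITY_R2_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# distributional and collinearity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Normality tests per variable, VIFs and correlations, LM test."""

    normality: pd.DataFrame  # index: variable; sw_stat, sw_p, ad_stat, ad_p, constant
    vif: pd.Series | None = None
    correlations: pd.DataFrame | None = None
    lm_statistic: float = float("nan")
    lm_p: float = float("nan")


def distribution_diagnostics(columns: pd.DataFrame) -> DiagnosticsReport:
    """Shapiro-Wilk and Anderson-Darling normality tests per column.

    Constant columns are flagged undefined (NaN statistics) rather than
    tested.  Requires at least 8 observations per column.
    """
    rows = {}
    for name, col in columns.items():
        x = col.dropna().to_numpy(dtype=float)
        if len(x) < 8:
            raise ValueError(f"column {name!r}: need >= 8 observations, got {len(x)}")
        if np.ptp(x) == 0:
            rows[name] = dict(sw_stat=np.nan, sw_p=np.nan, ad_stat=np.nan,
                              ad_p=np.nan, constant=True)
            continue
        sw = stats.shapiro(x)
        ad_stat, ad_p = normal_ad(x)
        rows[name] = dict(sw_stat=float(sw.statistic), sw_p=float(sw.pvalue),
                          ad_stat=float(ad_stat), ad_p=float(ad_p), constant=False)
    return DiagnosticsReport(normality=pd.DataFrame.from_dict(rows, orient="index"))


def collinearity_diagnostics(design: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Variance inflation factors and Pearson correlations.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j (plus intercept)
    on the remaining predictors; a perfectly collinear predictor gets an
    infinite VIF (with a warning).
    """
    if design.shape[1] < 2:
        raise ValueError("need >= 2 predictors for collinearity diagnostics")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than predictors")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    vifs = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(np.sum(resid**2))
        if sst == 0 or ssr / sst < 1e-12:
            warnings.warn(f"predictor {name!r} is (near-)perfectly collinear")
            vifs[name] = np.inf
        else:
            vifs[name] = 1.0 / (ssr / sst)
    return pd.Series(vifs, name="vif"), design.corr(method="pearson")


def heteroscedasticity_lm(residuals: np.ndarray, design: pd.DataFrame) -> tuple[float, float]:
    """Breusch-Pagan Lagrange-multiplier test for heteroscedasticity.

    LM = n * R^2 of the squared residuals regressed on the design,
    chi-square with df = number of predictors.  Zero-variance residuals
    leave the test undefined.
    """
    resid = np.asarray(residuals, dtype=float)
    if np.var(resid) == 0:
        raise ValueError("zero-variance residuals; LM test undefined")
    X = np.column_stack([np.ones(len(resid)), design.to_numpy(dtype=float)])
    lm, lm_p, _, _ = het_breuschpagan(resid, X)
    return float(lm), float(lm_p)


# ---------------------------------------------------------------------------
# GAM
# ---------------------------------------------------------------------------

@dataclass
class GAMResult:
    """Per-smooth-term p-values and the underlying statsmodels fit."""

    term_p: pd.Series
    edf: float
    fitted: np.ndarray
    results: object


def fit_duration_gam(
    lesions: pd.DataFrame,
    outcome: str,
    predictors: list[str] | None = None,
    df_per_term: int = 6,
    alpha: float | list[float] | None = None,
    select_penalty: bool = True,
) -> GAMResult:
    """Additive model of a duration on the lesion covariates.

    One univariate B-spline smooth (``df_per_term`` basis functions,
    cubic) per predictor plus an intercept; the smoothing penalty is
    selected per term by generalized cross-validation unless ``alpha``
    is given.  Per-term significance comes from a Wald test of that
    smooth's coefficient block.
    """
    predictors = predictors or [c for c in DEFAULT_PREDICTORS if c in lesions.columns]
    data = lesions[[outcome] + predictors].dropna()
    n = len(data)
    if n < 10 * len(predictors):
        raise ValueError(
            f"need >= {10 * len(predictors)} complete rows for {len(predictors)} "
            f"predictors, got {n}"
        )
    X = data[predictors].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(predictors) + 1:
        raise ValueError("rank-deficient design; drop collinear predictors")
    y = data[outcome].to_numpy(dtype=float)

    k = len(predictors)
    smoother = BSplines(X, df=[df_per_term] * k, degree=[3] * k)
    gam = GLMGam(y, exog=np.ones((n, 1)), smoother=smoother,
                 alpha=[1.0] * k if alpha is None else alpha)
    if alpha is None and select_penalty:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                gam.alpha = gam.select_penweight()[0]
            except Exception:  # keep the default penalty if selection fails
                pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = gam.fit()

    term_p = {}
    for i, name in enumerate(predictors):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tt = res.test_significance(smooth_index=i)
        term_p[name] = float(np.atleast_1d(tt.pvalue)[0])
    return GAMResult(
        term_p=pd.Series(term_p, name="gam_p"),
        edf=float(np.sum(res.edf)) if hasattr(res, "edf") else np.nan,
        fitted=np.asarray(res.fittedvalues),
        results=res,
    )


# ---------------------------------------------------------------------------
# random-forest importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Forest importances with their reliability context."""

    importances: pd.Series  # impurity-based, normalized to sum 1
    cv_mse: float
    cv_r2: float
    reliable: bool
    gam_p: pd.Series | None = None


def rf_importance(
    lesions: pd.DataFrame,
    outcome: str,
    predictors: list[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> ImportanceReport:
    """Random-forest regression: impurity importances + CV quality.

    Importances are normalized to sum to 1 over the predictor set.  The
    same fitted forest yields the importances and (via cross-validation
    with identical settings) the MSE/R^2 quality metrics; when the
    cross-validated R^2 falls below 0.2 a warning flags the importances
    as unreliable.
    """
    predictors = predictors or [c for c in DEFAULT_PREDICTORS if c in lesions.columns]
    data = lesions[[outcome] + predictors].dropna()
    n = len(data)
    if n < cv_folds:
        raise ValueError(f"{n} rows < {cv_folds} folds")
    X = data[predictors].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = -cross_val_score(forest, X, y, cv=cv, scoring="neg_mean_squared_error").mean()
    r2 = cross_val_score(forest, X, y, cv=cv, scoring="r2").mean()
    forest.fit(X, y)

    imp = forest.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    reliable = bool(r2 >= RELIABILITY_R2_THRESHOLD)
    if not reliable:
        warnings.warn(
            f"forest cross-validated R^2 = {r2:.3f} < {RELIABILITY_R2_THRESHOLD}; "
            "importances may be unreliable"
        )
    return ImportanceReport(
        importances=pd.Series(imp, index=predictors, name="importance"),
        cv_mse=float(mse),
        cv_r2=float(r2),
        reliable=reliable,
    )
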