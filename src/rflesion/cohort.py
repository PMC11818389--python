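"""Cohort-level statistics: exclusions, missing-data handling and the
paired comparison of RF application durations across stopping rules.

The lesion table (one row per lesion, schema of
:data:`rflesion.processing.LESION_TABLE_COLUMNS`) is first filtered by
the protocol exclusions (RF duration over 30 s, interlesion distance
over 6 mm).  Missing LSI durations — lesions whose predicted LSI never
reaches target within the trace — are assessed with Little's MCAR test
and completed by chained-equations imputation, with mean/median/kNN
comparators as a sensitivity analysis.  The three per-lesion durations
(AI-, LI- and LSI-guided) are then compared with the Friedman test and
post-hoc Wilcoxon signed-rank tests (Bonferroni-corrected, with Cohen's
effect size r = Z / sqrt(n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer

__all__ = [
    "ExclusionConfig",
    "ExclusionLog",
    "LittleMCARResult",
    "ImputationReport",
    "PairwiseResult",
    "CohortComparison",
    "apply_exclusions",
    "little_mcar_test",
    "impute_durations",
    "compare_durations",
    "summarize_cohort",
    "DURATION_COLUMNS",
    "IMPUTATION_PREDICTORS",
]

DURATION_COLUMNS = ["duration_ai_s", "duration_li_s", "duration_lsi_s"]

#: lesion covariates used as chained-equation predictors for the target
IMPUTATION_PREDICTORS = [
    "duration_li_s", "duration_ai_s", "cf_mean_g", "cf_start_g",
    "li_drop_ohm", "li_start_ohm",
]

#: the three post-hoc pairs; orientation (first - second) fixes the sign
#: of the effect size r
PAIRS = [("duration_ai_s", "duration_li_s"),
         ("duration_li_s", "duration_lsi_s"),
         ("duration_ai_s", "duration_lsi_s")]


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionConfig:
    """Protocol exclusion thresholds (strict 'over' excluded)."""

    max_duration_s: float = 30.0
    max_ild_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.max_duration_s <= 0 or self.max_ild_mm <= 0:
            raise ValueError("exclusion thresholds must be positive")


@dataclass(frozen=True)
class ExclusionLog:
    n_total: int
    n_duration_violations: int
    n_ild_violations: int
    n_overlap: int
    n_excluded: int

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def apply_exclusions(
    lesions: pd.DataFrame, cfg: ExclusionConfig = ExclusionConfig()
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop lesions over the duration or ILD thresholds.

    'Over' is strict: boundary values (exactly 30 s / 6 mm) are retained.
    The exclusion duration is the LI-guided (actually delivered) RF
    duration.  Missing ILD (singleton procedures) does not exclude.
    The two filters commute and the operation is idempotent.
    """
    dur_bad = lesions["duration_li_s"] > cfg.max_duration_s
    ild_bad = lesions["ild_mm"] > cfg.max_ild_mm
    bad = dur_bad | ild_bad
    log = ExclusionLog(
        n_total=len(lesions),
        n_duration_violations=int(dur_bad.sum()),
        n_ild_violations=int(ild_bad.sum()),
        n_overlap=int((dur_bad & ild_bad).sum()),
        n_excluded=int(bad.sum()),
    )
    return lesions.loc[~bad].copy(), log


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LittleMCARResult:
    chi2: float
    df: int
    p_value: float
    n_patterns: int


def _em_mvnorm(
    Y: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing entries.

    Standard EM: the E-step replaces missing entries by their conditional
    expectation given the observed ones and adds the conditional
    covariance to the second-moment statistics.
    """
    n, p = Y.shape
    miss = np.isnan(Y)
    mu = np.nanmean(Y, axis=0)
    filled = np.where(miss, mu, Y)
    sigma = np.cov(filled, rowvar=False, bias=True) + 1e-8 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)  # type: ignore[arg-type]
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    for _ in range(max_iter):
        Ey = Y.copy()
        extra = np.zeros((p, p))
        for key, idx in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            if not o.any():
                Ey[idx] = mu
                extra += len(idx) * sigma
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            Smm = sigma[np.ix_(m, m)]
            B = np.linalg.solve(Soo, Smo.T).T  # regression of missing on observed
            resid_cov = Smm - B @ Smo.T
            Ey[np.ix_(idx, m)] = mu[m] + (Y[np.ix_(idx, o)] - mu[o]) @ B.T
            cc = np.zeros((p, p))
            cc[np.ix_(m, m)] = resid_cov
            extra += len(idx) * cc
        mu_new = Ey.mean(axis=0)
        centered = Ey - mu_new
        sigma_new = (centered.T @ centered + extra) / n + 1e-10 * np.eye(p)
        if np.max(np.abs(mu_new - mu)) < tol and np.max(np.abs(sigma_new - sigma)) < tol:
            mu, sigma = mu_new, sigma_new
            break
        mu, sigma = mu_new, sigma_new
    return mu, sigma


def little_mcar_test(table: pd.DataFrame, max_iter: int = 100) -> LittleMCARResult:
    """Little's test of Missing Completely At Random.

    For each missingness pattern j with n_j rows and observed variable
    set o_j, the statistic sums the Mahalanobis distances of the pattern
    means from the EM grand means::

        d^2 = sum_j n_j (ybar_oj - mu_oj)' Sigma_oj^{-1} (ybar_oj - mu_oj)

    with df = sum_j |o_j| - p, referred to the chi-square upper tail.
    Rows that are entirely missing are dropped; a table with a single
    missingness pattern (e.g. no missing values) leaves the test
    undefined and raises.
    """
    num = table.select_dtypes(include=[np.number])
    Y = num.to_numpy(dtype=float)
    Y = Y[~np.isnan(Y).all(axis=1)]
    n, p = Y.shape
    miss = np.isnan(Y)
    keys = [m.tobytes() for m in miss]
    unique_keys = sorted(set(keys))
    if len(unique_keys) < 2:
        raise ValueError("Little's MCAR test undefined: only one missingness pattern")

    mu, sigma = _em_mvnorm(Y, max_iter=max_iter)
    d2 = 0.0
    df = -p
    for key in unique_keys:
        idx = np.asarray([i for i, k in enumerate(keys) if k == key])
        o = ~np.frombuffer(key, dtype=bool)
        df += int(o.sum())
        ybar = Y[np.ix_(idx, o)].mean(axis=0)
        diff = ybar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        d2 += len(idx) * float(diff @ np.linalg.solve(Soo, diff))
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else float("nan")
    return LittleMCARResult(chi2=float(d2), df=int(df), p_value=p_value,
                            n_patterns=len(unique_keys))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationReport:
    """Completed tables per method plus cross-method agreement.

    ``completed`` maps method name to a lesion table with no missing
    entries in the target column; ``agreement`` holds, for each
    comparator, an R^2-style concordance and an MAE-style discrepancy
    against the primary method, computed on the imputed cells only.
    """

    target_column: str
    primary_method: str
    iterations: int
    n_missing: int
    completed: dict[str, pd.DataFrame]
    agreement: pd.DataFrame
    mcar: LittleMCARResult | None = None

    @property
    def table(self) -> pd.DataFrame:
        """The primary method's completed table."""
        return self.completed[self.primary_method]


def _impute_matrix(
    M: np.ndarray, method: str, iterations: int, seed: int, n_multiple: int = 5
) -> np.ndarray:
    """Complete a numeric matrix; observed cells are never altered."""
    if method == "mice":
        draws = []
        for k in range(n_multiple):
            imp = IterativeImputer(
                max_iter=iterations, sample_posterior=True,
                random_state=seed + k, keep_empty_features=True,
            )
            draws.append(imp.fit_transform(M))
        return np.mean(draws, axis=0)
    if method in ("mean", "median"):
        stat = np.nanmean if method == "mean" else np.nanmedian
        out = M.copy()
        for j in range(M.shape[1]):
            col = out[:, j]
            col[np.isnan(col)] = stat(col)
        return out
    if method == "knn":
        mu = np.nanmean(M, axis=0)
        sd = np.nanstd(M, axis=0)
        sd[sd == 0] = 1.0
        Z = (M - mu) / sd
        return KNNImputer(n_neighbors=5).fit_transform(Z) * sd + mu
    raise ValueError(f"unknown imputation method {method!r}")


def impute_durations(
    table: pd.DataFrame,
    method: str = "mice",
    iterations: int = 5,
    seed: int = 0,
    target_column: str = "duration_lsi_s",
    predictors: list[str] | None = None,
    run_mcar_test: bool = True,
) -> ImputationReport:
    """Complete missing target durations and run the sensitivity analysis.

    The primary ``method`` (default chained equations, pooled over five
    imputations) and the three comparators (mean, median, kNN) each
    produce a completed table; agreement metrics between the primary and
    every comparator are computed on the imputed cells only.  Little's
    MCAR test is run on the target + predictor columns when at least two
    missingness patterns exist.
    """
    predictors = predictors or [c for c in IMPUTATION_PREDICTORS if c in table.columns]
    cols = predictors + [target_column]
    if target_column not in table.columns:
        raise ValueError(f"no target column {target_column!r}")
    missing_mask = table[target_column].isna()
    if missing_mask.all():
        raise ValueError("target column is entirely missing; cannot impute")

    mcar = None
    if run_mcar_test and missing_mask.any():
        try:
            mcar = little_mcar_test(table[cols])
        except ValueError:
            mcar = None

    M = table[cols].to_numpy(dtype=float)
    methods = [method] + [m for m in ("mice", "mean", "median", "knn") if m != method]
    completed: dict[str, pd.DataFrame] = {}
    for m in methods:
        filled = _impute_matrix(M, m, iterations, seed)
        out = table.copy()
        out[target_column] = np.where(missing_mask, filled[:, -1], M[:, -1])
        completed[m] = out

    rows = []
    cells = missing_mask.to_numpy()
    primary_vals = completed[method].loc[cells, target_column].to_numpy()
    for m in methods[1:]:
        other = completed[m].loc[cells, target_column].to_numpy()
        if cells.sum() == 0:
            r2c, mae = 1.0, 0.0
        else:
            denom = float(np.var(primary_vals))
            r2c = 1.0 - float(np.mean((primary_vals - other) ** 2)) / denom if denom > 0 else np.nan
            mae = float(np.mean(np.abs(primary_vals - other)))
        rows.append({"comparator": m, "concordance_r2": r2c, "discrepancy_mae": mae})
    agreement = pd.DataFrame(rows).set_index("comparator")

    return ImputationReport(
        target_column=target_column,
        primary_method=method,
        iterations=iterations,
        n_missing=int(cells.sum()),
        completed=completed,
        agreement=agreement,
        mcar=mcar,
    )


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    w_statistic: float
    p_raw: float
    p_bonferroni: float
    z_statistic: float
    effect_size_r: float
    n_nonzero: int


@dataclass
class CohortComparison:
    friedman_chi2: float
    friedman_p: float
    n_lesions: int
    pairwise: list[PairwiseResult]
    summary: pd.DataFrame


def _signed_rank(first: np.ndarray, second: np.ndarray) -> PairwiseResult:
    """Wilcoxon signed-rank with Cohen's r.

    Zero differences are dropped (Wilcoxon's original rule).  The p-value
    uses exact enumeration for n <= 25 without ties in |d|, otherwise the
    continuity-corrected normal approximation.  r = Z / sqrt(n) carries
    the sign of the median paired difference (first - second).
    """
    d = first - second
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; test degenerate")
        return PairwiseResult(("", ""), 0.0, 1.0, 1.0, 0.0, 0.0, 0)
    abs_ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    w = float(res.statistic)
    # z from the normal approximation regardless of the p-value method,
    # so the effect size is always defined
    mean_w = n * (n + 1) / 4.0
    tie_counts = pd.Series(abs_ranks).value_counts().to_numpy()
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0
    r = abs(z) / np.sqrt(n) * np.sign(np.median(first - second))
    return PairwiseResult(
        pair=("", ""),
        w_statistic=w,
        p_raw=float(res.pvalue),
        p_bonferroni=min(1.0, float(res.pvalue) * len(PAIRS)),
        z_statistic=float(z),
        effect_size_r=float(np.clip(r, -1.0, 1.0)),
        n_nonzero=n,
    )


def compare_durations(durations: pd.DataFrame) -> CohortComparison:
    """Friedman test plus post-hoc Wilcoxon tests on the three durations.

    ``durations`` must hold complete cases of the columns
    ``duration_ai_s``, ``duration_li_s``, ``duration_lsi_s`` (one row per
    lesion).  Pairwise p-values are Bonferroni-multiplied by the number
    of pairs (3, capped at 1); effect sizes follow the Cohen convention
    r = Z / sqrt(n), signed by the median paired difference of
    (first-listed - second-listed).
    """
    cols = DURATION_COLUMNS
    missing = set(cols) - set(durations.columns)
    if missing:
        raise ValueError(f"durations table missing columns {sorted(missing)}")
    data = durations[cols].dropna()
    n = len(data)
    if n < 5:
        raise ValueError(f"need >= 5 complete lesions, got {n}")

    arrays = [data[c].to_numpy(dtype=float) for c in cols]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        warnings.warn("all duration columns identical; Friedman statistic is 0")
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*arrays)

    pairwise = []
    for a, b in PAIRS:
        res = _signed_rank(data[a].to_numpy(dtype=float), data[b].to_numpy(dtype=float))
        pairwise.append(PairwiseResult(
            pair=(a, b), w_statistic=res.w_statistic, p_raw=res.p_raw,
            p_bonferroni=res.p_bonferroni, z_statistic=res.z_statistic,
            effect_size_r=res.effect_size_r, n_nonzero=res.n_nonzero,
        ))
    return CohortComparison(
        friedman_chi2=float(chi2),
        friedman_p=float(p),
        n_lesions=n,
        pairwise=pairwise,
        summary=summarize_cohort(data),
    )


def summarize_cohort(lesions: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR (Q1, Q3; linear-interpolation quantiles) per numeric
    column, the reporting convention for the lesion metrics."""
    if lesions.empty:
        raise ValueError("summarize_cohort: empty table")
    num = lesions.select_dtypes(include=[np.number])
    return pd.DataFrame({
        "median": num.median(),
        "q1": num.quantile(0.25, interpolation="linear"),
        "q3": num.quantile(0.75, interpolation="linear"),
    })
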