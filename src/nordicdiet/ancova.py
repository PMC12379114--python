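"""Quartile-group analysis: Quade's rank ANCOVA, adjusted means, trend test.

The outcome (HPL total) is heavily right-skewed, so group comparisons use
Quade's non-parametric analysis of covariance: outcome and covariates are
rank-transformed (mid-ranks for ties), covariate effects are removed by a
pooled least-squares fit on the ranks, and the residuals are compared
across diet-score quartiles with a one-way ANOVA F test on (k-1, N-k)
degrees of freedom.  Covariate-adjusted quartile means and their 95% CIs
come from the parallel parametric ANCOVA (OLS on the raw outcome,
evaluated at covariate sample means), and the trend test is a two-sided t
test of the linear quartile-index coefficient on the Quade residuals.

Covariate sets mirror the two adjustment models of the analysis:

* ``"model1"`` — age (years), examination year, energy intake (kJ/d)
* ``"model2"`` — model 1 plus leisure-time physical activity (kJ/d),
  adulthood socio-economic status (points), smoking (never/previous/
  current as two indicators, never = reference) and marital status
  (couple/other as one indicator, couple = reference)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diet_score import quartile_of

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "AncovaResult",
    "quartile_groups",
    "covariate_matrix",
    "quade_ancova",
    "adjusted_means",
    "trend_test",
    "impute_covariates",
]

MODEL1_COVARIATES = ("age", "exam_year", "energy_kj")
MODEL2_COVARIATES = MODEL1_COVARIATES + ("ltpa_kj", "ses", "smoking", "marital")

_MODEL_SETS = {"model1": MODEL1_COVARIATES, "model2": MODEL2_COVARIATES}


@dataclass
class AncovaResult:
    """Fitted quartile contrast for one covariate model."""

    model: str
    quade_F: float
    quade_p: float
    df: tuple[int, int]
    adjusted_means: pd.DataFrame          # quartile, n, adj_mean, ci_low, ci_high
    extreme_diff: float                   # lowest-adherence minus highest
    extreme_ci: tuple[float, float]
    extreme_p: float
    p_trend: float
    imputations: dict[str, int] = field(default_factory=dict)


def quartile_groups(scores) -> np.ndarray:
    """Quartile labels 1-4 of the diet score; 1 = lowest adherence.

    Uses the same quartile convention as the component scoring, so tied
    scores always share a group and group sizes may be unequal (the diet
    score's narrow integer range makes heavy ties the norm).
    """
    return quartile_of(np.asarray(scores, dtype=float))


def covariate_matrix(cohort: pd.DataFrame, covariate_set: str | tuple = "model2") -> pd.DataFrame:
    """Numeric design columns for a covariate set (no intercept).

    Categorical covariates are expanded to indicators: smoking ->
    ``smoking_previous``/``smoking_current`` (never = reference), marital
    -> ``marital_other`` (couple = reference).
    """
    names = _MODEL_SETS.get(covariate_set, covariate_set) if isinstance(covariate_set, str) else covariate_set
    cols = {}
    for name in names:
        if name == "smoking":
            cols["smoking_previous"] = (cohort["smoking"] == "previous").astype(float)
            cols["smoking_current"] = (cohort["smoking"] == "current").astype(float)
        elif name == "marital":
            cols["marital_other"] = (cohort["marital"] == "other").astype(float)
        else:
            cols[name] = pd.to_numeric(cohort[name], errors="raise").astype(float)
    X = pd.DataFrame(cols, index=cohort.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"covariates contain missing values after imputation: {bad}")
    return X


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _quade_residuals(outcome: np.ndarray, X: pd.DataFrame | None) -> np.ndarray:
    """Residuals of outcome ranks on covariate ranks (pooled OLS)."""
    r_y = _rank(outcome)
    if np.ptp(r_y) == 0:
        raise ValueError("degenerate design: outcome is constant (all ranks tied)")
    if X is None or X.shape[1] == 0:
        return r_y - r_y.mean()
    r_x = np.column_stack([_rank(X[c].to_numpy()) for c in X.columns])
    design = np.column_stack([np.ones(len(r_y)), r_x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient ranked covariates (rank {rank} < {design.shape[1]}); "
            f"columns: {list(X.columns)}"
        )
    beta, *_ = np.linalg.lstsq(design, r_y, rcond=None)
    return r_y - design @ beta


def _check_groups(groups: np.ndarray) -> list:
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("degenerate design: fewer than two occupied quartile groups")
    return levels


def quade_ancova(
    cohort: pd.DataFrame,
    groups,
    outcome: str = "hpl_total",
    covariate_set: str | tuple = "model2",
) -> tuple[float, float, tuple[int, int]]:
    """Quade's non-parametric ANCOVA F test across quartile groups.

    Returns ``(F, p, (df_num, df_den))`` where the p-value comes from the
    F distribution with (k-1, N-k) degrees of freedom.
    """
    groups = np.asarray(groups)
    levels = _check_groups(groups)
    y = cohort[outcome].to_numpy(dtype=float)
    X = covariate_matrix(cohort, covariate_set) if covariate_set else None
    resid = _quade_residuals(y, X)

    k, n = len(levels), len(resid)
    grand = resid.mean()
    ss_between = sum(
        (groups == g).sum() * (resid[groups == g].mean() - grand) ** 2 for g in levels
    )
    ss_within = sum(
        ((resid[groups == g] - resid[groups == g].mean()) ** 2).sum() for g in levels
    )
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        # all residual variation is between groups
        return float("inf"), 0.0, (df1, df2)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p, (df1, df2)


def adjusted_means(
    cohort: pd.DataFrame,
    groups,
    outcome: str = "hpl_total",
    covariate_set: str | tuple = "model2",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, tuple[float, float], float]:
    """Covariate-adjusted quartile means with CIs, and the extreme contrast.

    Ordinary least-squares ANCOVA of the raw outcome on quartile indicators
    plus covariates; adjusted means are model predictions at the covariate
    sample means.  The extreme difference is adjusted mean(lowest-adherence
    quartile) minus adjusted mean(highest), with a normal-theory CI and
    two-sided p from the contrast's standard error.
    """
    import statsmodels.api as sm

    groups = np.asarray(groups)
    levels = _check_groups(groups)
    y = cohort[outcome].to_numpy(dtype=float)
    X = covariate_matrix(cohort, covariate_set) if covariate_set else pd.DataFrame(index=cohort.index)

    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    dummy_names = [f"q{g}" for g in levels[1:]]
    design = np.column_stack([np.ones(len(y)), dummies, X.to_numpy()]) if X.shape[1] else \
        np.column_stack([np.ones(len(y)), dummies])
    names = ["intercept"] + dummy_names + list(X.columns)
    fit = sm.OLS(y, pd.DataFrame(design, columns=names)).fit()

    xbar = X.to_numpy().mean(axis=0) if X.shape[1] else np.empty(0)
    rows, contrasts = [], {}
    for g in levels:
        c = np.zeros(design.shape[1])
        c[0] = 1.0
        if g != levels[0]:
            c[1 + dummy_names.index(f"q{g}")] = 1.0
        c[1 + len(dummy_names):] = xbar
        contrasts[g] = c
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ fit.cov_params().to_numpy() @ c))
        tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
        rows.append(
            {"quartile": g, "n": int((groups == g).sum()), "adj_mean": est,
             "ci_low": est - tcrit * se, "ci_high": est + tcrit * se}
        )
    table = pd.DataFrame(rows)

    c = contrasts[levels[0]] - contrasts[levels[-1]]
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_params().to_numpy() @ c))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    pval = float(2 * stats.t.sf(abs(est) / se, fit.df_resid)) if se > 0 else float(est == 0.0)
    return table, est, (est - tcrit * se, est + tcrit * se), pval


def trend_test(
    cohort: pd.DataFrame,
    groups,
    outcome: str = "hpl_total",
    covariate_set: str | tuple = "model2",
) -> float:
    """P for linear trend across quartiles, within the Quade framework.

    The outcome ranks are residualised on the covariate ranks, then the
    residuals are regressed on the integer quartile index (1-4); the
    two-sided t-test p of the linear coefficient is returned.
    """
    groups = np.asarray(groups, dtype=float)
    _check_groups(groups)
    y = cohort[outcome].to_numpy(dtype=float)
    X = covariate_matrix(cohort, covariate_set) if covariate_set else None
    resid = _quade_residuals(y, X)
    slope, intercept, r, p, se = stats.linregress(groups, resid)
    return float(p)


def impute_covariates(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill covariate gaps by the stated single-value rules.

    Missing leisure-time physical activity is replaced by the cohort mean
    of the observed values; missing marital status by the modal category.
    Any other covariate with missing values raises (there is no stated rule
    for it).  Returns the imputed cohort and per-variable imputation counts.
    """
    out = cohort.copy()
    counts: dict[str, int] = {}

    n_ltpa = int(out["ltpa_kj"].isna().sum())
    if n_ltpa:
        observed = out["ltpa_kj"].dropna()
        if observed.empty:
            raise ValueError("cannot impute ltpa_kj: no observed values")
        out["ltpa_kj"] = out["ltpa_kj"].fillna(float(observed.mean()))
    counts["ltpa_kj"] = n_ltpa

    n_marital = int(out["marital"].isna().sum())
    if n_marital:
        observed = out["marital"].dropna()
        if observed.empty:
            raise ValueError("cannot impute marital: no observed values")
        out["marital"] = out["marital"].fillna(observed.mode().iloc[0])
    counts["marital"] = n_marital

    others = [c for c in ("age", "exam_year", "energy_kj", "ses", "smoking")
              if c in out.columns and out[c].isna().any()]
    if others:
        raise ValueError(f"no imputation rule for missing covariates: {others}")
    return out, counts


def run_ancova(
    cohort: pd.DataFrame,
    groups,
    outcome: str = "hpl_total",
    covariate_set: str = "model2",
) -> AncovaResult:
    """Convenience wrapper: Quade F/p, adjusted means and trend in one call."""
    F, p, df = quade_ancova(cohort, groups, outcome, covariate_set)
    table, diff, ci, diff_p = adjusted_means(cohort, groups, outcome, covariate_set)
    p_trend = trend_test(cohort, groups, outcome, covariate_set)
    return AncovaResult(
        model=covariate_set if isinstance(covariate_set, str) else "custom",
        quade_F=F, quade_p=p, df=df, adjusted_means=table,
        extreme_diff=diff, extreme_ci=ci, extreme_p=diff_p, p_trend=p_trend,
    )
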