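"""Cohort-level statistics: CoV equality, group tests, stepwise OLS models.

Between-subject variability of tissue medians is summarized by the
coefficient of variation (CoV = SD / mean) and compared across measures with
the asymptotic equality-of-CoVs chi-square test of Feltz & Miller:

    D = sum_i m_i (c_i - cbar)^2 / (cbar^2 (0.5 + cbar^2)),
    cbar = sum_i m_i c_i / sum_i m_i,   m_i = n_i - 1,

referred to a chi-square with k - 1 degrees of freedom. Group differences
use Welch t-tests (with the Welch-Satterthwaite df) and Pearson chi-square;
covariate models are ordinary least squares reduced by backward stepwise
removal of non-significant terms, with AIC-based selection along the path
and Cook's distance diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined for this input."""


def coefficient_of_variation(values) -> float:
    """Sample CoV in percent: 100 * SD (n-1 denominator) / mean."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("CoV requires at least two values")
    mean = x.mean()
    if mean == 0:
        raise DegenerateStatisticError("CoV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class CoVTestResult:
    """Equality-of-CoVs test result; CoVs echoed in percent."""

    covs: tuple
    ns: tuple
    statistic: float
    df: int
    p_value: float

    @property
    def cov_a(self) -> float:
        return self.covs[0]

    @property
    def cov_b(self) -> float:
        return self.covs[1]


def cov_equality_test(covs, ns) -> CoVTestResult:
    """Asymptotic chi-square test that k samples share one CoV.

    ``covs`` are the per-sample CoVs as *fractions* (not percent); ``ns``
    the sample sizes. The samples are treated as independent.
    """
    c = np.asarray(covs, dtype=np.float64)
    n = np.asarray(ns, dtype=np.int64)
    if c.size < 2 or c.size != n.size:
        raise ValueError("need k >= 2 matching CoVs and sample sizes")
    if np.any(n < 2):
        raise ValueError("each sample size must be >= 2")
    if np.all(c == 0):
        raise DegenerateStatisticError("all CoVs are zero; test degenerate")
    m = (n - 1).astype(np.float64)
    cbar = float((m * c).sum() / m.sum())
    statistic = float((m * (c - cbar) ** 2).sum() / (cbar**2 * (0.5 + cbar**2)))
    df = int(c.size - 1)
    p = float(sps.chi2.sf(statistic, df))
    return CoVTestResult(
        covs=tuple(100.0 * c), ns=tuple(int(v) for v in n), statistic=statistic, df=df, p_value=p
    )


def welch_t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Welch t, Welch-Satterthwaite df and two-sided p from summary stats."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be strictly positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("sample sizes must be >= 2")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(values_a, values_b):
    """Welch t-test on two samples; returns (t, df, p)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    return welch_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def chi_square_2x2(table):
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    res = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_with_adj_r2(x, y):
    """Pearson r plus the adjusted R^2 of the simple linear fit of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateStatisticError("correlation undefined for constant input")
    r = float(sps.pearsonr(x, y).statistic)
    n = x.size
    adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
    return r, float(adj)


class CollinearDesignError(RuntimeError):
    """The design matrix is rank deficient."""


@dataclass
class FittedModel:
    """One OLS fit along the stepwise path."""

    terms: tuple
    params: dict
    pvalues: dict
    term_pvalues: dict
    adj_r2: float
    resid_se: float
    f_stat: float
    f_df: tuple
    aic: float
    nobs: int
    max_cooks: float


@dataclass
class StepwiseModelResult:
    response: str
    models: list = field(default_factory=list)
    selected_index: int = 0

    @property
    def selected(self) -> FittedModel:
        return self.models[self.selected_index]


def cooks_distance_max(results) -> float:
    """Maximum Cook's distance over the observations of a fitted OLS model."""
    return float(OLSInfluence(results).cooks_distance[0].max())


def _fit_ols(data: pd.DataFrame, response: str, terms: dict) -> FittedModel:
    cols = [c for t in terms.values() for c in t]
    sub = data[[response] + cols].dropna()
    n = len(sub)
    if n < len(cols) + 2:
        raise ValueError(
            f"{n} complete cases for {len(cols)} terms; model underdetermined"
        )
    X = sm.add_constant(sub[cols].astype(np.float64), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearDesignError(f"collinear design for terms {sorted(terms)}")
    res = sm.OLS(sub[response].astype(np.float64), X).fit()
    pvalues = {k: float(v) for k, v in res.pvalues.items()}
    term_p = {t: max(pvalues[c] for c in cs) for t, cs in terms.items()}
    # AIC on the R convention: count the residual variance as a parameter.
    aic = float(-2.0 * res.llf + 2.0 * (res.df_model + 2))
    f_stat = float(res.fvalue) if cols else float("nan")
    return FittedModel(
        terms=tuple(terms),
        params={k: float(v) for k, v in res.params.items()},
        pvalues=pvalues,
        term_pvalues=term_p,
        adj_r2=float(res.rsquared_adj) if cols else 0.0,
        resid_se=float(np.sqrt(res.scale)),
        f_stat=f_stat,
        f_df=(int(res.df_model), int(res.df_resid)),
        aic=aic,
        nobs=int(res.nobs),
        max_cooks=cooks_distance_max(res),
    )


def backward_stepwise_ols(
    data: pd.DataFrame,
    response: str,
    terms: dict,
    removal_alpha: float = 0.05,
) -> StepwiseModelResult:
    """Backward stepwise OLS with AIC-based selection along the path.

    ``terms`` maps a term label to the design columns it binds together
    (an interaction pair such as Female:head / Male:head is one term and is
    removed as a unit; a term's p-value is the largest of its columns').
    Starting from the full model, the non-significant term with the largest
    p-value is removed and the model refit — with listwise deletion over the
    columns it still uses, so observation counts may grow along the path —
    until every remaining term is significant at ``removal_alpha``. The
    minimum-AIC model in the sequence is selected.
    """
    current = {t: list(c) for t, c in terms.items()}
    result = StepwiseModelResult(response=response)
    while True:
        fit = _fit_ols(data, response, current)
        result.models.append(fit)
        if not current:
            break
        worst = max(current, key=lambda t: fit.term_pvalues[t])
        if fit.term_pvalues[worst] < removal_alpha:
            break
        del current[worst]
    result.selected_index = int(np.argmin([m.aic for m in result.models]))
    return result
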