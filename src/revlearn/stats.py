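"""Statistical layer: t-tests, correlations, standardized regression, FDR.

Thin, explicitly-typed wrappers over scipy and statsmodels that return
the quantities reported in a cognitive-individual-differences analysis:
one-sample t with Cohen's d, Pearson r with Fisher-z confidence
intervals, fully standardized OLS coefficients with VIFs, and
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "RegressionResult",
    "one_sample_t",
    "pearson",
    "correlation_p_value",
    "standardized_regression",
    "vif",
    "bh_fdr",
    "parameter_regressions",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci: tuple[float, float]  # Fisher-z 95% interval
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """Standardized OLS fit: per-predictor effect sizes and diagnostics."""

    table: pd.DataFrame  # term, estimate, ci_low, ci_high, p, vif
    r_squared: float
    n: int

    def coefficient(self, term: str) -> pd.Series:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no such term: {term}")
        return row.iloc[0]


def one_sample_t(mean: float, sd: float, n: int, mu0: float) -> TTestResult:
    """One-sample t-test from summary statistics, with Cohen's d.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, d = (mean - mu0) / sd.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), d=float((mean - mu0) / sd))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t-transform."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must be strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with t-based p and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    p = correlation_p_value(r, n) if abs(r) < 1.0 else 0.0
    z = np.arctanh(r)
    zse = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(0.5 + ci_level / 2.0)
    ci = (float(np.tanh(z - zcrit * zse)), float(np.tanh(z + zcrit * zse)))
    return CorrelationResult(r=r, p=p, ci=ci, n=n)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def standardized_regression(y, X: pd.DataFrame, ci_level: float = 0.95) -> RegressionResult:
    """OLS with every variable z-scored, so coefficients are standardized b.

    Binary indicators (e.g. gender) are standardized along with the
    continuous predictors, giving every coefficient the same
    standardized-effect-size reading. CIs and p-values come from the
    usual OLS sampling distribution; VIFs from auxiliary regressions.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    if np.any(X.std(ddof=1).values == 0):
        bad = list(X.columns[X.std(ddof=1).values == 0])
        raise ValueError(f"constant predictor column(s): {bad}")
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < k:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"predictor table is rank deficient (e.g. {corr.index[i]!r} vs {corr.columns[j]!r})"
        )

    Xz = X.apply(lambda col: _zscore(col.to_numpy(dtype=float)))
    yz = _zscore(y)
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    conf = fit.conf_int(alpha=1.0 - ci_level)
    vifs = vif(X)
    rows = []
    for term in X.columns:
        rows.append(
            {
                "term": term,
                "estimate": float(fit.params[term]),
                "ci_low": float(conf.loc[term, 0]),
                "ci_high": float(conf.loc[term, 1]),
                "p": float(fit.pvalues[term]),
                "vif": float(vifs[term]),
            }
        )
    return RegressionResult(table=pd.DataFrame(rows), r_squared=float(fit.rsquared), n=n)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor (intercept included in the
    auxiliary regressions, as is standard for centered diagnostics)."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    arr = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("predictor table is rank deficient")
    values = [variance_inflation_factor(arr, j + 1) for j in range(X.shape[1])]
    return pd.Series(values, index=X.columns, name="vif")


def parameter_regressions(
    df: pd.DataFrame,
    outcomes: tuple[str, ...] = ("alpha_pos", "alpha_neg", "beta"),
    predictors: tuple[str, ...] = ("hardship_composite", "income", "age", "gender"),
    fdr_term: str = "hardship_composite",
) -> pd.DataFrame:
    """The study's regression layer: one standardized model per RL parameter.

    Each outcome (reward learning rate, punishment learning rate,
    inverse temperature) is regressed on hardship, income, age and
    gender simultaneously. BH-FDR adjustment is applied to the
    ``fdr_term`` coefficient's p-values *across the outcome family* —
    the three primary dependent variables — and reported as ``p_fdr``
    on those rows (NaN elsewhere).

    Returns a tidy table: outcome, term, estimate, ci_low, ci_high, p,
    p_fdr, vif, r_squared, n.
    """
    missing = [c for c in (*outcomes, *predictors) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    X = df.loc[:, list(predictors)]
    frames = []
    for outcome in outcomes:
        res = standardized_regression(df[outcome].to_numpy(dtype=float), X)
        tab = res.table.copy()
        tab.insert(0, "outcome", outcome)
        tab["r_squared"] = res.r_squared
        tab["n"] = res.n
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    table["p_fdr"] = np.nan
    fam = table["term"] == fdr_term
    if fam.any():
        table.loc[fam, "p_fdr"] = bh_fdr(table.loc[fam, "p"].to_numpy())
    return table


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted
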