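"""Confirmatory statistics: MANCOVA with Wilks' lambda, Bonferroni,
Pearson correlations with Fisher-z intervals, and demographic group tests.

The MANCOVA models each response (marker expression after missing-value
substitution) by an intercept, a single group contrast and covariates
(age, centered; sex as a 0/1 indicator).  The group effect is tested
multivariately with Wilks' lambda, Λ = det(E) / det(E + H) where E and H
are the residual and hypothesis cross-product matrices.  For a single-df
hypothesis the exact F transform is

    F = ((1 − Λ) / Λ) · (n − q − p + 1) / p     ~  F(p, n − q − p + 1)

with p responses and q model terms; univariate follow-up F tests have
df (1, n − q) and are Bonferroni-corrected within the configured family.
Multi-df hypotheses (e.g. both covariates jointly) use Rao's F
approximation, which is exact when min(p, h) <= 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import NumericalError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Wilks' lambda machinery
# ---------------------------------------------------------------------------

@dataclass
class WilksTest:
    """A Wilks' lambda test of one hypothesis block."""

    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p_value: float
    hypothesis_df: int


def _wilks_f(lmbda: float, p: int, h: int, error_df: int) -> WilksTest:
    """Rao's F transform of Wilks' lambda (exact for min(p, h) <= 2)."""
    if not 0.0 < lmbda <= 1.0 + 1e-12:
        raise NumericalError(f"Wilks lambda out of (0, 1]: {lmbda}")
    lmbda = min(lmbda, 1.0)
    if h == 1:
        df1 = p
        df2 = error_df - p + 1
        F = (1.0 - lmbda) / lmbda * df2 / df1
    else:
        denom = p * p + h * h - 5
        t = np.sqrt((p * p * h * h - 4.0) / denom) if denom > 0 else 1.0
        w = error_df - (p - h + 1) / 2.0
        df1 = p * h
        df2 = w * t - (df1 - 2) / 2.0
        lam_t = lmbda ** (1.0 / t)
        F = (1.0 - lam_t) / lam_t * df2 / df1
    if df2 <= 0:
        raise NumericalError("non-positive denominator df; too many responses")
    p_value = float(stats.f.sf(F, df1, df2))
    return WilksTest(float(lmbda), float(F), float(df1), float(df2),
                     p_value, h)


def _cross_products(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual cross-product matrix of Y on the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T @ resid


# ---------------------------------------------------------------------------
# MANCOVA
# ---------------------------------------------------------------------------

@dataclass
class MancovaResult:
    group_test: WilksTest
    covariate_test: WilksTest | None
    univariate: pd.DataFrame  # per response: F, df1, df2, p, p_adjusted, significant
    n: int
    n_responses: int
    n_model_terms: int
    alpha: float
    family_size: int

    @property
    def error_df(self) -> int:
        return self.n - self.n_model_terms


def _design(group: pd.Series, control_label: str, case_label: str,
            covariates: pd.DataFrame | None) -> tuple[np.ndarray, int]:
    n = len(group)
    cols = [np.ones(n), (group == case_label).to_numpy(dtype=float)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or str(col.dtype) == "category":
                levels = sorted(col.astype(str).unique())
                if len(levels) > 2:
                    raise ValidationError(
                        f"covariate {name!r} has more than two levels")
                cols.append((col.astype(str) == levels[-1]).to_numpy(float))
            else:
                v = col.to_numpy(dtype=float)
                cols.append(v - v.mean())  # center metric covariates
    X = np.column_stack(cols)
    return X, X.shape[1]


def mancova(responses: pd.DataFrame, group: pd.Series,
            covariates: pd.DataFrame | None = None,
            control_label: str = "control", case_label: str = "case",
            alpha: float = DEFAULT_ALPHA,
            family_size: int | None = None) -> MancovaResult:
    """Multivariate analysis of covariance for a two-group contrast.

    Parameters
    ----------
    responses
        samples x p table of marker values, no missing cells (substitute
        upstream).
    group
        per-sample group labels aligned to ``responses.index``.
    covariates
        optional per-sample covariates (metric columns are centered,
        two-level string columns coded 0/1), e.g. age and sex.
    family_size
        Bonferroni family for the univariate follow-ups; defaults to the
        number of responses.
    """
    if responses.isna().to_numpy().any():
        raise ValidationError("responses contain missing values; substitute first")
    group = group.reindex(responses.index)
    if covariates is not None:
        covariates = covariates.reindex(responses.index)
    Y = responses.to_numpy(dtype=float)
    n, p = Y.shape
    X, q = _design(group, control_label, case_label, covariates)
    if n <= q + p:
        raise ValidationError(
            f"need n > q + p (n={n}, model terms q={q}, responses p={p})")

    E = _cross_products(Y, X)
    X_nogroup = np.delete(X, 1, axis=1)
    H = _cross_products(Y, X_nogroup) - E
    detE = np.linalg.det(E)
    if detE <= 0:
        raise NumericalError(
            "singular residual cross-product matrix; reduce the number of "
            "responses or remove collinear markers")
    lmbda = detE / np.linalg.det(E + H)
    group_test = _wilks_f(lmbda, p, 1, n - q)

    covariate_test = None
    if covariates is not None and covariates.shape[1] > 0:
        h_cov = covariates.shape[1]
        X_nocov = X[:, :2]
        H_cov = _cross_products(Y, X_nocov) - E
        lam_cov = detE / np.linalg.det(E + H_cov)
        covariate_test = _wilks_f(lam_cov, p, h_cov, n - q)

    # univariate follow-ups: F(1, n - q) per response
    err_df = n - q
    E_diag = np.diag(E)
    H_diag = np.diag(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        F_uni = H_diag / (E_diag / err_df)
    p_uni = stats.f.sf(F_uni, 1, err_df)
    fam = family_size if family_size is not None else p
    decisions = bonferroni(pd.Series(p_uni, index=responses.columns),
                           family_size=fam, alpha=alpha)
    univariate = pd.DataFrame({
        "F": F_uni, "df1": 1, "df2": err_df, "p_value": p_uni,
        "p_adjusted": decisions["p_adjusted"],
        "significant": decisions["significant"],
    }, index=responses.columns)

    logger.info("MANCOVA: Wilks lambda %.4f, F(%g, %g) = %.2f, p = %.3g",
                group_test.wilks_lambda, group_test.df1, group_test.df2,
                group_test.F, group_test.p_value)
    return MancovaResult(group_test, covariate_test, univariate,
                         n, p, q, alpha, fam)


def bonferroni(p_values: pd.Series, family_size: int | None = None,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Bonferroni decisions: reject iff p < alpha / m; adjusted p = min(1, m p)."""
    m = family_size if family_size is not None else len(p_values)
    if m < 1:
        raise ValidationError("family size must be >= 1")
    return pd.DataFrame({
        "p_value": p_values,
        "p_adjusted": np.minimum(1.0, m * p_values),
        "significant": p_values < alpha / m,
    })


# ---------------------------------------------------------------------------
# Pearson correlation with Fisher-z CI
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    ci_level: float
    r_squared: float  # fraction of variance explained

    @property
    def r_squared_percent(self) -> int:
        return variance_explained_percent(self.r)


def variance_explained_percent(r: float) -> int:
    """Share of variance explained by a correlation, as an integer percent."""
    return int(round(100.0 * r * r))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValidationError("Fisher CI needs n >= 4")
    if not -1.0 < r < 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1.0 - (1.0 - level) / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson(x: np.ndarray, y: np.ndarray, ci_level: float = 0.95,
            cq: np.ndarray | None = None,
            cq_cutoff: float | None = None) -> CorrelationResult:
    """Pearson correlation with t-based p and Fisher-z CI.

    ``cq``/``cq_cutoff`` optionally restrict the pairs to samples whose raw
    Cq for the marker lies at or below an inclusion cutoff (e.g. 32 cycles)
    before correlating.  Pairs with a missing member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    if cq is not None and cq_cutoff is not None:
        cq = np.asarray(cq, dtype=float)
        keep &= ~np.isnan(cq) & (cq <= cq_cutoff)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValidationError(f"need >= 4 paired observations, have {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise NumericalError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    lo, hi = fisher_ci(r, n, ci_level)
    return CorrelationResult(r, n, p, lo, hi, ci_level, r * r)


# ---------------------------------------------------------------------------
# Demographic tests
# ---------------------------------------------------------------------------

def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test from group summaries (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("t-test needs >= 2 samples per group")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def demographics_tests(meta: "pd.DataFrame", control_label: str = "control",
                       case_label: str = "case",
                       equal_var: bool = True) -> pd.DataFrame:
    """Group comparisons of the metadata: t-tests for metric columns,
    chi-square for sex counts.

    Returns one row per variable with the statistic, p-value and group
    summaries (mean ± SD, or f/m counts for sex).
    """
    group = meta["group"]
    g1 = meta[group == control_label]
    g2 = meta[group == case_label]
    if len(g1) == 0 or len(g2) == 0:
        raise ValidationError("both groups must be non-empty")
    rows = []
    for col in meta.columns:
        if col == "group":
            continue
        if col == "sex":
            table = pd.crosstab(meta["group"], meta["sex"])
            chi2, p, _, _ = stats.chi2_contingency(table)
            rows.append((col, "chi2", float(chi2), float(p),
                         "/".join(str(v) for v in table.loc[control_label]),
                         "/".join(str(v) for v in table.loc[case_label])))
            continue
        x = pd.to_numeric(g1[col], errors="coerce").dropna()
        y = pd.to_numeric(g2[col], errors="coerce").dropna()
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(
                f"variable {col!r}: need >= 2 values per group for a t-test")
        if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(x, y, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append((col, "t", t, p,
                     f"{x.mean():.1f} ± {x.std():.1f}",
                     f"{y.mean():.1f} ± {y.std():.1f}"))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                       "p_value", "control_summary",
                                       "case_summary"]).set_index("variable")
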