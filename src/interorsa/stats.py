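"""Inferential battery for two-group psychophysiology cohorts.

Covers the analyses this literature runs on a (group x covariates x
physiology) cohort table: independent t-tests, normality gating, Pearson
and mid-rank Spearman correlations with Bonferroni thresholds, Fisher
r-to-z comparison of two independent correlations, between-subjects
ANCOVA with adjusted marginal means, a 2x2x2 within x group mixed ANOVA
with Tukey post hocs, reciprocal normalization for distance ratings,
standardized simple regression, and Mahalanobis outlier screening.

Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
Spearman p-values are two-sided by default (the one-sided tail is also
reported on the result object).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "CorrelationResult",
    "ZComparison",
    "RegressionResult",
    "AncovaResult",
    "independent_t_test",
    "shapiro_wilk",
    "pearson",
    "spearman",
    "fisher_rz_compare",
    "bonferroni_threshold",
    "ancova",
    "mixed_anova",
    "tukey_hsd",
    "reciprocal_normalize",
    "simple_regression",
    "mahalanobis_outliers",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    p_one_sided: float
    kind: str = "pearson"

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class ZComparison:
    """Fisher r-to-z test for two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    """Simple regression with a standardized slope.

    With one predictor, ``b`` equals Pearson r, ``R2 = b**2`` and
    ``F = t**2`` identically.
    """

    b: float
    t: float
    F: float
    r2: float
    adj_r2: float
    n: int
    p: float


@dataclass
class AncovaResult:
    table: pd.DataFrame
    marginal_means: pd.DataFrame
    covariate_values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def independent_t_test(x, y, two_sided: bool = True):
    """Pooled-variance independent-samples t-test.

    Returns (t, df, p).  Degenerate samples (zero pooled variance with a
    nonzero mean difference) raise rather than returning an infinite t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    diff = float(np.mean(x) - np.mean(y))
    if sp2 <= 0:
        if diff == 0:
            return 0.0, df, 1.0
        raise ValueError("degenerate samples: zero pooled variance")
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * _st.t.sf(abs(t), df) if two_sided else _st.t.sf(t, df)
    return float(t), df, float(p)


def shapiro_wilk(x):
    """Shapiro-Wilk normality test; the gate for choosing Spearman."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("too few observations for Shapiro-Wilk (n >= 3)")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: constant sample")
    res = _st.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _corr_p(r: float, n: int) -> tuple[float, float]:
    """Two- and one-sided p from the t transform of a correlation."""
    if abs(r) >= 1.0:
        return 0.0, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    two = 2 * _st.t.sf(abs(t), n - 2)
    one = two / 2
    return float(two), float(one)


def pearson(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    two, one = _corr_p(r, x.size)
    return CorrelationResult(r, x.size, two, one, "pearson")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson applied to mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    rx = _st.rankdata(x, method="average")
    ry = _st.rankdata(y, method="average")
    base = pearson(rx, ry)
    return CorrelationResult(base.r, base.n, base.p, base.p_one_sided, "spearman")


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> ZComparison:
    """Compare two independent correlations via the Fisher transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("transform undefined for |r| >= 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * _st.norm.sf(abs(z))
    return ZComparison(r1, n1, r2, n2, float(z), float(p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold for a family of ``m`` planned tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _partial_eta_sq(tab: pd.DataFrame) -> pd.Series:
    ss_err = float(tab.loc["Residual", "sum_sq"])
    return tab["sum_sq"] / (tab["sum_sq"] + ss_err)


def ancova(
    data: pd.DataFrame,
    dv: str,
    group: str,
    covariates: list[str],
    at: dict[str, float] | None = None,
) -> AncovaResult:
    """Between-subjects ANCOVA (general linear model) with marginal means.

    F tests (Type II) for the group factor and each covariate, partial
    eta squared per effect, and adjusted group means evaluated with the
    covariates held at ``at`` (default: their grand means).  Covariates
    without variance carry no information and are dropped with a warning,
    so the model gracefully reduces to a one-way ANOVA.
    """
    df = data[[dv, group] + covariates].dropna().copy()
    kept = []
    for c in covariates:
        if np.ptp(df[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"covariate {c!r} is constant and was dropped", stacklevel=2)
        else:
            kept.append(c)
    rhs = " + ".join([f"C(Q('{group}'))"] + [f"Q('{c}')" for c in kept]) or "1"
    model = smf.ols(f"Q('{dv}') ~ {rhs}", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    tab = tab.rename(
        index={f"C(Q('{group}'))": group, **{f"Q('{c}')": c for c in kept}}
    )
    tab["eta_sq_partial"] = _partial_eta_sq(tab)
    tab["df_den"] = float(tab.loc["Residual", "df"])

    at_vals = {c: float(df[c].mean()) for c in kept}
    if at:
        at_vals.update({c: float(v) for c, v in at.items() if c in at_vals})
    import patsy

    levels = sorted(df[group].unique())
    rows = []
    for lev in levels:
        pred = pd.DataFrame([{group: lev, **at_vals}])
        (exog,) = patsy.build_design_matrices([model.model.data.design_info], pred)
        exog = np.asarray(exog)
        mean = float((exog @ np.asarray(model.params))[0])
        se = float(np.sqrt((exog @ np.asarray(model.cov_params()) @ exog.T)[0, 0]))
        rows.append({group: lev, "adjusted_mean": mean, "se": se})
    mm = pd.DataFrame(rows)
    return AncovaResult(tab, mm, at_vals)


# ---------------------------------------------------------------------------
# Mixed (within x between) ANOVA
# ---------------------------------------------------------------------------

def _check_complete(wide: pd.DataFrame, cells: list[tuple]) -> None:
    for subj, row in wide.iterrows():
        missing = [c for c in cells if pd.isna(row[c])]
        if missing:
            raise ValueError(f"incomplete design: subject {subj!r} missing cell(s) {missing}")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    between: str,
    subject: str,
) -> pd.DataFrame:
    """Mixed ANOVA for fully crossed 2-level within factors x one between
    factor (two groups).

    Uses the exact contrast decomposition valid for 2-level factors: each
    within effect reduces to a per-subject contrast score, whose
    unweighted-group-mean test gives the within effect and whose group
    comparison gives its interaction with the between factor; the between
    effect is the one-way ANOVA on subject means.  F values agree with the
    classical subject-stratified mixed-model ANOVA.

    Returns a table with effect, F, df_num, df_den, p, eta_sq_partial.
    """
    for w in within:
        if data[w].nunique() != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")
    groups = sorted(data[between].unique())
    if len(groups) != 2:
        raise ValueError("between factor must have exactly 2 levels")

    levels = {w: sorted(data[w].unique()) for w in within}
    cells = list(itertools.product(*[levels[w] for w in within]))
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if len(within) == 1:
        wide.columns = [(c,) for c in wide.columns]
    _check_complete(wide, cells)
    grp = (
        data[[subject, between]]
        .drop_duplicates()
        .set_index(subject)[between]
        .reindex(wide.index)
    )
    g = np.where(grp == groups[0], 0.5, -0.5)  # effect coding
    n_subj = wide.shape[0]
    df_den = n_subj - 2

    rows = []

    def _f_test(values: np.ndarray, test: str) -> tuple[float, float, float]:
        """F for the intercept (unweighted mean) or slope of values ~ g."""
        X = np.column_stack([np.ones_like(g), g])
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        resid = values - X @ beta
        ss_err = float(resid @ resid)
        mse = ss_err / df_den
        xtx_inv = np.linalg.inv(X.T @ X)
        idx = 0 if test == "mean" else 1
        scale = float(values @ values) + 1.0
        if mse < 1e-24 * scale:  # error variance is numerically zero
            F = 0.0 if beta[idx] ** 2 < 1e-24 * scale else np.inf
        else:
            se = np.sqrt(mse * xtx_inv[idx, idx])
            t = beta[idx] / se
            F = float(t * t)
        p = float(_st.f.sf(F, 1, df_den))
        eta = F / (F + df_den)
        return F, p, eta

    # Between effect: subject means.
    means = wide.to_numpy(dtype=float).mean(axis=1)
    F, p, eta = _f_test(means, "slope")
    rows.append((between, F, 1, df_den, p, eta))

    # Within effects and their interactions with the between factor.
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            signs = []
            for cell in cells:
                s = 1.0
                for w, lev in zip(within, cell):
                    if w in combo and lev != levels[w][0]:
                        s *= -1.0
                signs.append(s)
            signs = np.asarray(signs)
            contrast = (wide.to_numpy(dtype=float) * signs).mean(axis=1)
            name = " x ".join(combo)
            F, p, eta = _f_test(contrast, "mean")
            rows.append((name, F, 1, df_den, p, eta))
            F, p, eta = _f_test(contrast, "slope")
            rows.append((f"{name} x {between}", F, 1, df_den, p, eta))

    return pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "p", "eta_sq_partial"]
    )


def tukey_hsd(data: pd.DataFrame, dv: str, cell: str) -> pd.DataFrame:
    """Tukey(-Kramer) HSD over the cells of ``cell``.

    q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) against the
    studentized-range distribution with k cells and the one-way error df.
    """
    cells = sorted(data[cell].unique())
    k = len(cells)
    if k < 2:
        raise ValueError("need at least 2 cells")
    vals = {c: data.loc[data[cell] == c, dv].to_numpy(dtype=float) for c in cells}
    ns = {c: v.size for c, v in vals.items()}
    n_tot = sum(ns.values())
    df_err = n_tot - k
    if df_err < 1:
        raise ValueError("no error degrees of freedom")
    mse = sum(float(np.sum((v - v.mean()) ** 2)) for v in vals.values()) / df_err
    rows = []
    for a, b in itertools.combinations(cells, 2):
        diff = float(vals[a].mean() - vals[b].mean())
        se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(_st.studentized_range.sf(q, k, df_err))
        rows.append({"cell_a": a, "cell_b": b, "diff": diff, "q": q, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transforms, regression, outliers
# ---------------------------------------------------------------------------

def reciprocal_normalize(distance):
    """1/x normalization for comfort distances (cm); reporting stays in cm."""
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("invalid distance: must be positive")
    out = 1.0 / d
    return float(out) if np.isscalar(distance) else out


def simple_regression(y, x) -> RegressionResult:
    """OLS of y on one predictor, reported on the standardized scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    if np.ptp(y) == 0:
        raise ValueError("degenerate criterion: zero variance")
    n = x.size
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(zx)).fit()
    b = float(model.params[1])
    t = float(model.tvalues[1])
    r2 = float(model.rsquared)
    return RegressionResult(
        b=b,
        t=t,
        F=float(t * t),
        r2=r2,
        adj_r2=float(model.rsquared_adj),
        n=n,
        p=float(model.pvalues[1]),
    )


def mahalanobis_outliers(data: pd.DataFrame, alpha: float = 0.001) -> pd.Series:
    """Flag multivariate outliers by squared Mahalanobis distance.

    Distances are referred to the chi-square quantile at 1 - alpha with
    as many degrees of freedom as columns.  Labelled stand-in for manual
    outlier screening; the flag, not an exclusion, is returned.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} variables")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular covariance")
    inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", X - mu, inv, X - mu)
    crit = _st.chi2.ppf(1 - alpha, df=p)
    return pd.Series(d2 > crit, index=data.index, name="outlier")
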