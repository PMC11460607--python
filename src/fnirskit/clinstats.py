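"""Clinical/demographic statistics and shared inference utilities.

Covers one-way ANOVA and two-sample t tests computed directly from group
summary statistics (mean, sd, n) — the form in which published demographic
tables report them — plus Pearson chi-square tests for categorical rows,
Benjamini-Hochberg FDR control used by every channel/pair family in the
pipeline, normality-gated correlation, and outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe import GROUPS

#: Plausible instrument score ranges used when truncating simulated scores.
SCALE_BOUNDS = {
    "HAMD24": (0.0, 76.0),
    "SDSS": (0.0, 20.0),
    "MOCA": (0.0, 30.0),
    "taichi_score": (0.0, 100.0),
    "age": (18.0, 100.0),
    "height": (120.0, 210.0),
    "weight": (30.0, 150.0),
    "t2dm_duration": (0.0, 60.0),
}


@dataclass(frozen=True)
class SummaryGroup:
    """Moments of one group: mean, standard deviation, sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


def anova_from_summary(groups: Sequence[SummaryGroup]) -> AnovaResult:
    """One-way ANOVA from per-group (mean, sd, n).

    F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N - k)],
    identical to the raw-data F whenever the raw data has these moments.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    m = np.array([g.mean for g in groups], float)
    s = np.array([g.sd for g in groups], float)
    n = np.array([g.n for g in groups], float)
    k, N = len(groups), n.sum()
    grand = (n * m).sum() / N
    ms_between = (n * (m - grand) ** 2).sum() / (k - 1)
    ss_within = ((n - 1) * s**2).sum()
    if ss_within <= 0:
        raise ValueError("zero within-group variance in every group")
    ms_within = ss_within / (N - k)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, k - 1, N - k))
    return AnovaResult(F=float(F), p=p, df_between=k - 1, df_within=int(N - k))


def t_from_summary(
    a: SummaryGroup, b: SummaryGroup, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sample t from summaries; pooled-variance by default, Welch optional."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("zero variance in both groups")
    va, vb = a.sd**2, b.sd**2
    if pooled:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    t = (a.mean - b.mean) / se
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), p, float(df)


def chi_square_test(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square on an r x c contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a nonnegative 2-D array of counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = row @ col / total
    if np.any(expected <= 0):
        raise ValueError("zero expected count")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p, df


def fdr_bh(p_values: Iterable[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection mask).

    q_i = min over j >= rank(i) of p_(j) * m / j, clipped to 1; rejections
    are all hypotheses at or below the largest rank r with p_(r) <= r*alpha/m.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    passed = p[order] <= alpha * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        cutoff = np.max(np.flatnonzero(passed))
        reject[order[: cutoff + 1]] = True
    return q, reject


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(r)
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    method: str  # "pearson" or "spearman"


def correlate_gated(x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05) -> CorrelationResult:
    """Correlation with a normality gate: Shapiro-Wilk on both variables at
    ``normality_alpha`` selects Pearson (both normal) or Spearman otherwise;
    the two-sided p comes from the t transform of the coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable")
    normal = (
        stats.shapiro(x).pvalue > normality_alpha
        and stats.shapiro(y).pvalue > normality_alpha
    )
    if normal:
        r = float(np.corrcoef(x, y)[0, 1])
        method = "pearson"
    else:
        r = float(stats.spearmanr(x, y).statistic)
        method = "spearman"
    return CorrelationResult(r=r, p=correlation_pvalue(r, x.size), method=method)


def exclude_outliers(
    x: np.ndarray,
    y: np.ndarray,
    rule: str = "studentized",
    z_max: float = 3.0,
    iqr_k: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Outlier exclusion for a bivariate correlation sample.

    "studentized": points whose internally studentized residual from the
    least-squares line y ~ x exceeds ``z_max`` in magnitude are dropped.
    "iqr": points outside median +/- iqr_k * IQR on either variable.
    Returns (retained indices, excluded indices); refuses to drop more than
    half the data.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need matched samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable")
    if rule == "studentized":
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        h = np.diag(H)
        s2 = resid @ resid / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = resid / np.sqrt(s2 * np.maximum(1 - h, 1e-12))
        excluded = np.flatnonzero(np.abs(t) > z_max)
    elif rule == "iqr":
        bad = np.zeros(n, dtype=bool)
        for v in (x, y):
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            bad |= (v < q1 - iqr_k * iqr) | (v > q3 + iqr_k * iqr)
        excluded = np.flatnonzero(bad)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if excluded.size > n / 2:
        raise ValueError("rule would exclude more than half the data")
    retained = np.setdiff1d(np.arange(n), excluded)
    return retained, excluded


def demographic_table(clinical: pd.DataFrame, pooled_t: bool = True) -> pd.DataFrame:
    """Group-comparison report over a clinical table.

    Continuous variables are compared across the three groups with
    one-way ANOVA on their computed moments (or a two-sample t test when
    only two groups carry the variable, as for diabetes duration);
    categorical variables use the Pearson chi-square test on group counts.
    Returns one row per variable with per-group 'mean +/- sd' (or counts),
    the test statistic, and its p-value.
    """
    if "group" not in clinical.columns:
        raise ValueError("clinical table needs a 'group' column")
    groups = [g for g in GROUPS if g in set(clinical["group"])]
    if len(groups) < 2:
        out_rows = []
        for col in clinical.columns:
            if col in ("subject_id", "group") or not pd.api.types.is_numeric_dtype(clinical[col]):
                continue
            v = clinical[col].dropna()
            out_rows.append(
                {"variable": col, "test": "none", "statistic": np.nan, "p": np.nan,
                 **{f"{clinical['group'].iloc[0]}": f"{v.mean():.2f} +/- {v.std(ddof=1):.2f}"}}
            )
        return pd.DataFrame(out_rows)

    rows = []
    for col in clinical.columns:
        if col in ("subject_id", "group"):
            continue
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series):
            summaries, cells = [], {}
            for g in groups:
                v = series[clinical["group"] == g].dropna().to_numpy(float)
                if v.size >= 2:
                    sg = SummaryGroup(float(v.mean()), float(v.std(ddof=1)), v.size)
                    summaries.append(sg)
                    cells[g] = f"{sg.mean:.2f} +/- {sg.sd:.2f}"
                else:
                    cells[g] = "-"
            if len(summaries) >= 3:
                res = anova_from_summary(summaries)
                rows.append({"variable": col, "test": "anova", "statistic": res.F,
                             "p": res.p, **cells})
            elif len(summaries) == 2:
                t, p, _ = t_from_summary(summaries[0], summaries[1], pooled=pooled_t)
                rows.append({"variable": col, "test": "t", "statistic": t, "p": p, **cells})
        else:
            sub = clinical.dropna(subset=[col])
            counts = pd.crosstab(sub["group"], sub[col])
            counts = counts.loc[[g for g in groups if g in counts.index]]
            cells = {g: "/".join(str(int(c)) for c in counts.loc[g]) if g in counts.index else "-"
                     for g in groups}
            try:
                chi2, p, _ = chi_square_test(counts.to_numpy())
                rows.append({"variable": col, "test": "chi2", "statistic": chi2, "p": p, **cells})
            except ValueError:
                rows.append({"variable": col, "test": "chi2", "statistic": np.nan,
                             "p": np.nan, **cells})
    return pd.DataFrame(rows)
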