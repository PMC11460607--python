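"""GLM activation analysis: canonical HRF design, per-channel beta
estimation, and group-level channel statistics with FDR control.

The task regressor is the block boxcar (four 15 s blocks = 60 s of task)
convolved with the canonical double-gamma hemodynamic response function
and scaled to unit peak, so a beta of b means a peak task-evoked
concentration change of b umol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._groupcompare import omnibus_with_posthoc, welch_t
from .probe import GROUPS, ProbeLayout, TaskParadigm


def canonical_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma canonical HRF sampled at times ``t`` (s), peak-normalised.

    h(t) = g(t; peak) - ratio * g(t; undershoot) with unit-scale gamma
    densities; the SPM-convention shape used by NIRS GLM toolkits.
    """
    t = np.asarray(t, float)
    h = np.zeros_like(t)
    pos = t > 0
    for shape, w in ((peak_s, 1.0), (undershoot_s, -ratio)):
        logpdf = (shape - 1) * np.log(t[pos]) - t[pos] - gammaln(shape)
        h[pos] += w * np.exp(logpdf)
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def task_regressor(
    paradigm: TaskParadigm,
    hrf: np.ndarray | None = None,
    per_block: bool = False,
) -> np.ndarray:
    """Boxcar(s) over the task blocks convolved with the HRF, unit peak.

    Returns shape (n_samples,) for the single 60 s regressor (default) or
    (n_blocks, n_samples) when ``per_block`` is set.
    """
    n = paradigm.n_samples
    if hrf is None:
        hrf = canonical_hrf(np.arange(int(32 * paradigm.fs)) / paradigm.fs)
    blen = int(round(paradigm.block_duration_s * paradigm.fs))
    onsets = paradigm.block_onsets_samples
    boxes = np.zeros((paradigm.n_blocks, n))
    for i, on in enumerate(onsets):
        boxes[i, on : on + blen] = 1.0
    if not per_block:
        boxes = boxes.sum(axis=0, keepdims=True)
    out = np.empty_like(boxes)
    for i in range(boxes.shape[0]):
        conv = np.convolve(boxes[i], hrf)[:n]
        m = np.max(np.abs(conv))
        out[i] = conv / m if m > 0 else conv
    return out[0] if not per_block else out


@dataclass
class DesignMatrix:
    """GLM design: columns (task [or blocks], intercept, optional drift)."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def task_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.startswith("task")]


def build_design(
    paradigm: TaskParadigm,
    hrf: np.ndarray | None = None,
    drift: bool = True,
    per_block: bool = False,
) -> DesignMatrix:
    """Assemble the design matrix for one subject."""
    reg = task_regressor(paradigm, hrf=hrf, per_block=per_block)
    reg = np.atleast_2d(reg)
    n = paradigm.n_samples
    cols = [reg.T]
    names = (
        [f"task_block{i + 1}" for i in range(reg.shape[0])] if per_block else ["task"]
    )
    cols.append(np.ones((n, 1)))
    names.append("intercept")
    if drift:
        t = np.linspace(-1, 1, n)[:, None]
        cols.append(t)
        names.append("drift")
    return DesignMatrix(matrix=np.hstack(cols), columns=tuple(names))


def filter_design(
    design: DesignMatrix,
    band_hz: tuple[float, float],
    order: int,
    fs: float,
) -> DesignMatrix:
    """Apply the analysis band-pass to every non-intercept regressor.

    When the data have been band-pass filtered, the evoked component in
    the data is filter(beta * regressor) = beta * filter(regressor), so
    fitting against the identically filtered regressor leaves beta on the
    original amplitude scale and removes the attenuation bias a raw
    regressor would suffer.
    """
    from .preprocess import bandpass_filter

    X = design.matrix.copy()
    for i, name in enumerate(design.columns):
        if name != "intercept":
            X[:, i] = bandpass_filter(X[:, i], band_hz, order, fs)
    return DesignMatrix(matrix=X, columns=design.columns)


@dataclass
class GLMFit:
    """Per-series OLS estimates: task beta(s), all coefficients, residual variance."""

    beta_task: np.ndarray
    coefficients: np.ndarray
    residual_variance: np.ndarray
    dof: int


def fit_glm(y: np.ndarray, design: DesignMatrix, prewhiten: bool = False) -> GLMFit:
    """Ordinary least squares per channel; optional AR(1) prewhitening.

    ``y`` is (time,) or (channels, time).  With ``prewhiten`` the lag-1
    autocorrelation of the OLS residuals drives a Cochrane-Orcutt
    transform before refitting.  The task beta is the coefficient of the
    (first) task column; with a per-block design it is the mean over blocks.
    """
    y = np.atleast_2d(np.asarray(y, float))
    X = design.matrix
    if y.shape[-1] != X.shape[0]:
        raise ValueError(f"series length {y.shape[-1]} != design rows {X.shape[0]}")

    def _ols(Xm: np.ndarray, ym: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        coef, *_ = np.linalg.lstsq(Xm, ym.T, rcond=None)
        resid = ym - (Xm @ coef).T
        dof = Xm.shape[0] - Xm.shape[1]
        return coef.T, resid.var(axis=-1, ddof=0) * ym.shape[-1] / max(dof, 1)

    coef, rvar = _ols(X, y)
    if prewhiten:
        resid = y - (X @ coef.T).T
        num = (resid[:, 1:] * resid[:, :-1]).sum()
        den = (resid[:, :-1] ** 2).sum()
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
        Xw = X[1:] - rho * X[:-1]
        yw = y[:, 1:] - rho * y[:, :-1]
        coef, rvar = _ols(Xw, yw)
    task_idx = design.task_columns
    beta_task = coef[:, task_idx].mean(axis=1)
    return GLMFit(
        beta_task=np.squeeze(beta_task),
        coefficients=np.squeeze(coef),
        residual_variance=np.squeeze(rvar),
        dof=X.shape[0] - X.shape[1],
    )


def one_sample_t(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t test against 0: t = mean / (sd/sqrt(n)), df = n - 1."""
    values = np.asarray(values, float)
    n = values.shape[axis]
    if n < 2:
        raise ValueError("need n >= 2")
    sd = values.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        # zero spread only matters when the mean is nonzero; t=0/0 otherwise
        mean = values.mean(axis=axis)
        if np.any((sd == 0) & (mean != 0)):
            raise ValueError("zero variance with nonzero mean: t undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = values.mean(axis=axis) / (sd / np.sqrt(n))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def group_one_sample_t(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-channel one-sample t of beta against zero."""
    rows = []
    for (group, channel), sub in beta_table.groupby(["group", "channel"], sort=True):
        t, p = one_sample_t(sub["beta"].to_numpy())
        rows.append({"group": group, "channel": channel, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def _betas_by_group(beta_table: pd.DataFrame) -> dict[str, np.ndarray]:
    pivot = beta_table.pivot_table(
        index=["group", "subject_id"], columns="channel", values="beta"
    ).sort_index(axis=1)
    return {
        g: pivot.loc[g].to_numpy()
        for g in GROUPS
        if g in pivot.index.get_level_values(0)
    }


def channel_anova(beta_table: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Channel-wise one-way ANOVA of beta across the three groups.

    Omnibus p-values are BH-corrected over the 40-channel family; Welch
    post hoc contrasts are reported only for channels surviving the
    omnibus, BH-corrected over the three contrasts within channel.
    Returns (omnibus table, post hoc table).
    """
    groups = _betas_by_group(beta_table)
    if len(groups) < 3:
        missing = set(GROUPS) - set(groups)
        raise ValueError(f"missing group(s) for ANOVA: {sorted(missing)}")
    res = omnibus_with_posthoc(groups, alpha=alpha)
    channels = sorted(beta_table["channel"].unique())
    omnibus = pd.DataFrame(
        {"channel": channels, "F": res["F"], "p": res["p"], "q": res["q"],
         "significant": res["significant"]}
    )
    ph_rows = []
    for pair, tvals in res["posthoc_t"].items():
        for i, ch in enumerate(channels):
            ph_rows.append(
                {"channel": ch, "group_a": pair[0], "group_b": pair[1],
                 "t": tvals[i], "p": res["posthoc_p"][pair][i],
                 "q": res["posthoc_q"][pair][i]}
            )
    return omnibus, pd.DataFrame(ph_rows)


def roi_summary(channel_t: pd.DataFrame, layout: ProbeLayout) -> pd.DataFrame:
    """Mean channel t per ROI per group (the ROI activation summary)."""
    roi_of = layout.roi_map()
    df = channel_t.copy()
    df["roi"] = df["channel"].map(roi_of)
    if df["roi"].isna().any():
        raise ValueError("ROI map does not cover all channels in the table")
    out = df.groupby(["group", "roi"], sort=True)["t"].mean().reset_index()
    return out.rename(columns={"t": "mean_t"})
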