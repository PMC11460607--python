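"""Internal vectorised group-comparison machinery.

One-way ANOVA and Welch pairwise t tests applied feature-wise (features =
channels, channel pairs, or regions), with Benjamini-Hochberg correction
over the omnibus family and, within each surviving feature, over the three
pairwise contrasts.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from .clinstats import fdr_bh


def anova_oneway(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Feature-wise one-way ANOVA.  Each element of ``groups`` is an
    (n_subjects, n_features) array; returns (F, p) of shape (n_features,)."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    groups = [np.atleast_2d(np.asarray(g, float)) for g in groups]
    n = np.array([g.shape[0] for g in groups], float)
    if np.any(n < 2):
        raise ValueError("need at least 2 subjects per group")
    N = n.sum()
    means = np.stack([g.mean(axis=0) for g in groups])          # (k, f)
    grand = (n[:, None] * means).sum(axis=0) / N
    ss_between = (n[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = np.stack(
        [((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means)]
    ).sum(axis=0)
    ms_between = ss_between / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_within = ss_within / (N - k)
        F = np.where(ms_within > 0, ms_between / np.where(ms_within > 0, ms_within, 1.0), np.inf)
    F = np.where((ms_within == 0) & (ms_between == 0), 0.0, F)
    p = stats.f.sf(F, k - 1, N - k)
    return F, p


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Feature-wise Welch two-sample t test on (n, f) arrays."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(se2 > 0, df, na + nb - 2)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def omnibus_with_posthoc(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Omnibus ANOVA per feature + FDR, then Welch post hoc on survivors.

    ``groups`` maps group label -> (n_subjects, n_features).  The omnibus
    p-values are BH-corrected across features; pairwise contrasts are run
    only for features whose omnibus q < alpha and BH-corrected within
    feature across the contrasts.  Returns a dict of arrays:
    F, p, q, significant (bool), and posthoc {(ga, gb): (t, p, q)} with NaN
    where the omnibus did not survive.
    """
    labels = list(groups)
    arrays = [np.atleast_2d(np.asarray(groups[g], float)) for g in labels]
    F, p = anova_oneway(arrays)
    q, reject = fdr_bh(p, alpha)
    pairs = list(combinations(labels, 2))
    ph_t = {pair: np.full(F.shape, np.nan) for pair in pairs}
    ph_p = {pair: np.full(F.shape, np.nan) for pair in pairs}
    ph_q = {pair: np.full(F.shape, np.nan) for pair in pairs}
    for pair in pairs:
        ia, ib = labels.index(pair[0]), labels.index(pair[1])
        t, pp = welch_t(arrays[ia], arrays[ib])
        ph_t[pair] = t
        ph_p[pair] = pp
    for f in np.flatnonzero(reject):
        ps = np.array([ph_p[pair][f] for pair in pairs])
        qs, _ = fdr_bh(ps, alpha)
        for pair, qv in zip(pairs, qs):
            ph_q[pair][f] = qv
    for pair in pairs:  # contrasts are only reported where the omnibus survives
        ph_t[pair][~reject] = np.nan
        ph_p[pair][~reject] = np.nan
    return {
        "labels": labels,
        "F": F,
        "p": p,
        "q": q,
        "significant": reject,
        "posthoc_t": ph_t,
        "posthoc_p": ph_p,
        "posthoc_q": ph_q,
    }
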