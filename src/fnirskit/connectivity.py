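"""Phase-locking-value (PLV) functional connectivity.

The instantaneous phase of each band-limited HbO2 trace comes from its
analytic signal (Hilbert transform); for a channel pair (a, b),

    PLV = | (1/N) sum_t exp( i (phi_a(t) - phi_b(t)) ) |,

computed over the 60 s task window with 10% of the window trimmed at each
end to limit transform edge effects.  PLV is 1 for perfectly phase-locked
pairs and tends to the Rayleigh mean sqrt(pi)/(2 sqrt(N)) for independent
phases.  Group differences are assessed pair-wise (780 unique pairs) with
one-way ANOVA and BH-FDR over the pair family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ._groupcompare import omnibus_with_posthoc
from .preprocess import HemoglobinSeries
from .probe import TaskParadigm, extract_task_window


def instantaneous_phase(series: np.ndarray) -> np.ndarray:
    """Phase (radians) of the analytic signal along the last axis.

    The input must be band-limited (the narrowband assumption is what
    makes the analytic-signal phase meaningful); constant traces have no
    defined phase and are rejected.
    """
    x = np.asarray(series, float)
    ptp = x.max(axis=-1) - x.min(axis=-1)
    if np.any(ptp <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("constant or nonfinite trace: phase undefined")
    return np.angle(hilbert(x, axis=-1))


def plv_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV of two phase series: magnitude of the mean phase-difference phasor."""
    phase_a = np.asarray(phase_a, float)
    phase_b = np.asarray(phase_b, float)
    if phase_a.shape != phase_b.shape or phase_a.size < 2:
        raise ValueError("phase series must have equal length >= 2")
    return float(np.abs(np.exp(1j * (phase_a - phase_b)).mean()))


def plv_matrix(
    hemo: HemoglobinSeries,
    paradigm: TaskParadigm,
    edge_trim: float = 0.1,
) -> np.ndarray:
    """Symmetric PLV matrix over all channel pairs in the task window.

    Phase is extracted on the full record (better Hilbert edge behaviour),
    then the task window is sliced and ``edge_trim`` of it is dropped at
    each end before averaging phasors.
    """
    phase = instantaneous_phase(hemo.hbo2)
    task_phase = extract_task_window(phase, paradigm, axis=-1)
    n = task_phase.shape[-1]
    k = int(round(edge_trim * n))
    if n - 2 * k < 2:
        raise ValueError("task window too short after edge trimming")
    z = np.exp(1j * task_phase[..., k : n - k])
    m = np.abs(z @ z.conj().T) / z.shape[-1]
    np.fill_diagonal(m, 1.0)
    m = np.clip((m + m.T) / 2, 0.0, 1.0)
    return m


def pair_index(n_channels: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) indices of the unique channel pairs."""
    return np.triu_indices(n_channels, k=1)


def pairwise_group_compare(
    plv_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of PLV per channel pair across groups.

    ``plv_by_group`` maps group -> (n_subjects, n_channels, n_channels)
    stacks of per-subject PLV matrices.  Omnibus p-values are BH-corrected
    over the 780-pair family; Welch post hoc contrasts are corrected within
    pair for surviving pairs.  Returns a long-format table
    (ch_i, ch_j, F, p, q, significant, and per-contrast t/p/q columns)
    with 1-based channel ids.
    """
    first = next(iter(plv_by_group.values()))
    nch = first.shape[-1]
    iu, ju = pair_index(nch)
    flat = {g: np.asarray(m, float)[:, iu, ju] for g, m in plv_by_group.items()}
    res = omnibus_with_posthoc(flat, alpha=alpha)
    out = pd.DataFrame(
        {"ch_i": iu + 1, "ch_j": ju + 1, "F": res["F"], "p": res["p"],
         "q": res["q"], "significant": res["significant"]}
    )
    for pair in res["posthoc_t"]:
        tag = f"{pair[0]}_vs_{pair[1]}"
        out[f"t_{tag}"] = res["posthoc_t"][pair]
        out[f"p_{tag}"] = res["posthoc_p"][pair]
        out[f"q_{tag}"] = res["posthoc_q"][pair]
    return out
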