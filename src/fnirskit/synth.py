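"""Synthetic three-group fNIRS cohort generator with known ground truth.

Forward model per subject:

* evoked HbO2 per channel = (block boxcar * canonical HRF, unit peak)
  scaled by the group-and-ROI effect amplitude (umol/L) and a hemispheric
  factor implementing the configured left/right dominance ratio;
* HbO2 phase coupling: channels in a coupling block mix a shared
  narrowband (0.01-0.1 Hz) oscillator with an independent one at the
  block's strength m in [0, 1] (m = 1 -> identical phases, m = 0 ->
  independent);
* physiological noise: cardiac, respiratory and Mayer-wave sinusoids with
  random phases, white noise, and a random linear drift;
* motion artifacts: Poisson-timed one-sample spikes (10 sd) and step
  baseline shifts (5 sd) persisting to the end of the record;
* Hb = -r HbO2 (default r = 0.3), and intensities
  I = I0 * 10**(-dOD) with dOD from the forward modified Beer-Lambert law,
  so the full inverse pipeline can be exercised end to end.

Clinical scores are drawn from group-specific truncated normals calibrated
to published cohort summaries for elderly T2DM/depression samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activation import task_regressor
from .config import AnalysisConfig
from .laterality import REGIONS, laterality_index
from .preprocess import bandpass_filter, mbll_forward
from .probe import GROUPS, ProbeLayout, TaskParadigm, RawRecording, default_layout
from .clinstats import SCALE_BOUNDS

#: Task-responsive ROIs carrying the group effect (prefrontal + motor core).
EFFECT_ROIS = ("FPA", "DLPFC", "Broca", "PMC", "STG", "SMA")

#: Default peak evoked dHbO2 (umol/L) per group in the effect ROIs; the
#: remaining ROIs respond weakly and identically across groups.  Ordering
#: HEALTHY > T2DM > T2DM_MDD encodes the hypoactivation of the depressed
#: diabetic group.
DEFAULT_EFFECT_AMPLITUDE = {"HEALTHY": 1.0, "T2DM": 0.7, "T2DM_MDD": 0.4}
BASELINE_ROI_AMPLITUDE = 0.2

#: Left/right amplitude ratio per group: healthy controls left-dominant,
#: the depressed group right-dominant (negative LI).
DEFAULT_LATERALITY_FACTOR = {"HEALTHY": 1.3, "T2DM": 1.1, "T2DM_MDD": 0.7}

#: Clinical score calibration per group: scale -> (mean, sd).
DEFAULT_CLINICAL = {
    "T2DM_MDD": {
        "age": (68.85, 3.67), "height": (163.10, 7.06), "weight": (55.85, 10.28),
        "t2dm_duration": (10.08, 4.77), "HAMD24": (22.90, 2.67),
        "SDSS": (4.45, 2.50), "MOCA": (27.75, 0.55), "taichi_score": (83.40, 1.05),
    },
    "T2DM": {
        "age": (67.90, 7.74), "height": (164.65, 6.89), "weight": (60.60, 7.37),
        "t2dm_duration": (12.20, 3.98), "HAMD24": (3.25, 2.43),
        "SDSS": (1.00, 1.45), "MOCA": (27.60, 0.68), "taichi_score": (83.30, 1.08),
    },
    "HEALTHY": {
        "age": (65.85, 3.18), "height": (161.45, 5.54), "weight": (58.40, 6.85),
        "t2dm_duration": None, "HAMD24": (3.75, 1.45),
        "SDSS": (0.35, 0.59), "MOCA": (27.70, 0.66), "taichi_score": (83.20, 1.11),
    },
}
DEFAULT_MALE_FRACTION = {"T2DM_MDD": 12 / 30, "T2DM": 15 / 30, "HEALTHY": 13 / 30}


@dataclass
class NoiseSpec:
    """Physiological noise model, amplitudes in umol/L on the HbO2 trace."""

    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.2
    respiratory_amp: float = 0.1
    mayer_amp: float = 0.1
    osc_amp: float = 0.15  # in-band background driving phase coupling
    white_sd: float = 0.1
    drift_slope: float = 0.002  # umol/L per second, sd of the random slope

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0,
                   osc_amp=0.0, white_sd=0.0, drift_slope=0.0)


@dataclass
class CouplingBlock:
    """A set of channels sharing a narrowband oscillator at given strength.

    ``strength`` is either a single mixing coefficient in [0, 1] or a map
    group -> coefficient (to weaken coupling in one group only).
    """

    channel_ids: tuple[int, ...]
    strength: float | dict[str, float]

    def strength_for(self, group: str) -> float:
        s = self.strength[group] if isinstance(self.strength, dict) else self.strength
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"coupling strength {s} outside [0, 1]")
        return float(s)


def _default_coupling_blocks() -> list[CouplingBlock]:
    # one prefrontal block whose coupling drops by 0.4 in the depressed group
    return [CouplingBlock(channel_ids=(1, 2, 3, 4, 5),
                          strength={"HEALTHY": 0.8, "T2DM": 0.8, "T2DM_MDD": 0.4})]


@dataclass
class CohortSpec:
    """Generator settings for one synthetic cohort."""

    n_per_group: int = 30
    effect_amplitude: dict = field(
        default_factory=lambda: {
            g: {roi: (DEFAULT_EFFECT_AMPLITUDE[g] if roi in EFFECT_ROIS
                      else BASELINE_ROI_AMPLITUDE)
                for roi in ("DLPFC", "Broca", "FPA", "OA", "FEF",
                            "SMA", "PMC", "PSC", "STG", "Wernicke")}
            for g in GROUPS
        }
    )
    laterality_factor: dict = field(default_factory=lambda: dict(DEFAULT_LATERALITY_FACTOR))
    coupling_blocks: list = field(default_factory=_default_coupling_blocks)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifact_rate_per_min: float = 0.5
    spike_sd: float = 10.0
    shift_sd: float = 5.0
    hb_ratio: float = 0.3
    i0: float = 1.0
    clinical: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CLINICAL.items()})
    male_fraction: dict = field(default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g, rois in self.effect_amplitude.items():
            for roi, a in rois.items():
                if not np.isfinite(a):
                    raise ValueError(f"amplitude for {g}/{roi} not finite")
        for b in self.coupling_blocks:
            for g in GROUPS:
                b.strength_for(g)


@dataclass
class SubjectTruth:
    """Ground truth kept by the generator for recovery tests."""

    subject_id: str
    group: str
    true_beta: np.ndarray          # (n_channels,) peak evoked dHbO2, umol/L
    clean_hbo2: np.ndarray         # (n_channels, n_samples) noiseless evoked trace
    true_li: dict                  # region -> LI of the clean evoked response
    coupling: list                 # (channel_ids, strength) per block


@dataclass
class SyntheticTruth:
    subjects: list

    def beta_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for ch, b in enumerate(s.true_beta, start=1):
                rows.append({"subject_id": s.subject_id, "group": s.group,
                             "channel": ch, "true_beta": float(b)})
        return pd.DataFrame(rows)


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], order: int) -> np.ndarray:
    """Unit-sd band-limited Gaussian noise (the coupling oscillator)."""
    x = bandpass_filter(rng.standard_normal(n), band, order, fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(
    spec: CohortSpec,
    group: str,
    seed: int,
    layout: ProbeLayout | None = None,
    paradigm: TaskParadigm | None = None,
    config: AnalysisConfig | None = None,
    subject_id: str | None = None,
) -> tuple[RawRecording, SubjectTruth]:
    """Generate one subject's raw recording and its ground truth."""
    if seed is None:
        raise ValueError("a seed is required: generation must be reproducible")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    layout = layout or default_layout()
    paradigm = paradigm or TaskParadigm()
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    n = paradigm.n_samples
    fs = paradigm.fs
    t = paradigm.times()
    nch = layout.n_channels

    reg = task_regressor(paradigm)
    ratio = float(spec.laterality_factor.get(group, 1.0))
    hemi_factor = np.array(
        [np.sqrt(ratio) if c.hemisphere == "left" else 1.0 / np.sqrt(ratio)
         for c in layout.channels]
    )
    amp = np.array([spec.effect_amplitude[group][c.roi] for c in layout.channels])
    true_beta = amp * hemi_factor
    clean = true_beta[:, None] * reg[None, :]

    ns = spec.noise
    noise = np.zeros((nch, n))
    # shared/independent narrowband oscillators drive phase coupling
    if ns.osc_amp > 0:
        osc = np.empty((nch, n))
        block_of = {}
        for b in spec.coupling_blocks:
            common = _narrowband(rng, n, fs, config.band_hz, config.filter_order)
            for ch in b.channel_ids:
                block_of[ch] = (common, b.strength_for(group))
        for i, c in enumerate(layout.channels):
            indep = _narrowband(rng, n, fs, config.band_hz, config.filter_order)
            if c.channel_id in block_of:
                common, m = block_of[c.channel_id]
                osc[i] = m * common + (1.0 - m) * indep
            else:
                osc[i] = indep
        noise += ns.osc_amp * osc
    for f_hz, a in ((ns.cardiac_hz, ns.cardiac_amp),
                    (ns.respiratory_hz, ns.respiratory_amp),
                    (ns.mayer_hz, ns.mayer_amp)):
        if a > 0:
            phase = rng.uniform(0, 2 * np.pi, size=(nch, 1))
            noise += a * np.sin(2 * np.pi * f_hz * t[None, :] + phase)
    if ns.white_sd > 0:
        noise += ns.white_sd * rng.standard_normal((nch, n))
    if ns.drift_slope > 0:
        slope = rng.normal(0.0, ns.drift_slope, size=(nch, 1))
        noise += slope * t[None, :]

    hbo2 = clean + noise
    # Poisson-timed motion artifacts per channel
    if spec.artifact_rate_per_min > 0:
        lam = spec.artifact_rate_per_min * paradigm.total_duration_s / 60.0
        for i in range(nch):
            for _ in range(rng.poisson(lam)):
                sd = hbo2[i].std()
                pos = int(rng.integers(0, n))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                if rng.random() < 0.7:
                    hbo2[i, pos] += sign * spec.spike_sd * sd
                else:
                    hbo2[i, pos:] += sign * spec.shift_sd * sd

    hb = -spec.hb_ratio * hbo2
    od = mbll_forward(hbo2, hb, config.extinction,
                      separation_cm=float(layout.separations_cm[0]), dpf=config.dpf)
    intensity = spec.i0 * 10.0 ** (-np.moveaxis(od, 0, 1))  # (ch, wl, time)

    sid = subject_id or f"sub-{seed}"
    rec = RawRecording(subject_id=sid, group=group, intensity=intensity,
                       fs=fs, events=paradigm.block_onsets_samples)

    start, stop = paradigm.task_window
    true_li = {}
    for region in REGIONS:
        L = float(clean[layout.region_indices(region, "left"), start:stop].mean())
        R = float(clean[layout.region_indices(region, "right"), start:stop].mean())
        true_li[region] = laterality_index(L, R)
    truth = SubjectTruth(
        subject_id=sid, group=group, true_beta=true_beta, clean_hbo2=clean,
        true_li=true_li,
        coupling=[(b.channel_ids, b.strength_for(group)) for b in spec.coupling_blocks],
    )
    return rec, truth


def _sample_score(rng: np.random.Generator, mean: float, sd: float,
                  bounds: tuple[float, float], size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_clinical(spec: CohortSpec, rng: np.random.Generator,
                      subject_ids: dict[str, list[str]]) -> pd.DataFrame:
    """Clinical table for the cohort: truncated-normal scores per group."""
    frames = []
    for group, ids in subject_ids.items():
        k = len(ids)
        cols: dict = {"subject_id": ids, "group": group}
        cols["sex"] = np.where(
            rng.random(k) < spec.male_fraction.get(group, 0.5), "male", "female"
        )
        for scale, ms in spec.clinical[group].items():
            if ms is None:
                cols[scale] = np.full(k, np.nan)
                continue
            mean, sd = ms
            bounds = SCALE_BOUNDS.get(scale, (-np.inf, np.inf))
            cols[scale] = _sample_score(rng, mean, sd, bounds, k)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    spec: CohortSpec,
    layout: ProbeLayout | None = None,
    paradigm: TaskParadigm | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[list[RawRecording], SyntheticTruth, pd.DataFrame]:
    """Generate 3 x n_per_group subjects, their ground truth, and clinical scores."""
    layout = layout or default_layout()
    paradigm = paradigm or TaskParadigm()
    config = config or AnalysisConfig()
    master = np.random.default_rng(spec.seed)
    seeds = master.integers(0, 2**31 - 1, size=3 * spec.n_per_group)
    recordings, truths = [], []
    subject_ids: dict[str, list[str]] = {g: [] for g in GROUPS}
    i = 0
    for group in GROUPS:
        for j in range(spec.n_per_group):
            sid = f"{group}-{j + 1:03d}"
            rec, truth = simulate_subject(
                spec, group, int(seeds[i]), layout, paradigm, config, subject_id=sid
            )
            recordings.append(rec)
            truths.append(truth)
            subject_ids[group].append(sid)
            i += 1
    clinical = simulate_clinical(spec, master, subject_ids)
    return recordings, SyntheticTruth(subjects=truths), clinical
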