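"""Probe geometry, task paradigm, and core domain types.

The montage modelled here is a 16-source x 16-detector prefrontal/motor
layout yielding 40 measurement channels, each a source-detector pair at
2.5 cm separation sampled at 5 Hz with two wavelengths (760 and 850 nm).
Twenty channels sit over the left hemisphere (CH1-CH9, CH11, CH31-CH40)
and twenty over the right (CH10, CH12-CH30).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GROUPS = ("T2DM_MDD", "T2DM", "HEALTHY")

ROI_LABELS = (
    "DLPFC", "Broca", "FPA", "OA", "FEF",
    "SMA", "PMC", "PSC", "STG", "Wernicke",
)

#: ROIs aggregated into the two laterality regions.
PREFRONTAL_ROIS = frozenset({"DLPFC", "Broca", "FPA", "OA"})
MOTOR_ROIS = frozenset({"SMA", "PMC", "PSC", "FEF", "STG", "Wernicke"})

#: 1-based channel ids over the left hemisphere; the remaining 20 are right.
LEFT_CHANNEL_IDS = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 11} | set(range(31, 41)))

#: Default channel -> ROI assignment.  Each of the ten areas is bilateral:
#: two left-hemisphere and two right-hemisphere channels, drawn as
#: contiguous pairs from the left/right channel sets above.  The true
#: per-channel anatomical map is montage-specific and should be supplied
#: via config when known; this balanced default guarantees every ROI and
#: both laterality regions are represented equally in each hemisphere.
DEFAULT_ROI_BLOCKS = {
    "DLPFC": (1, 2, 10, 12),
    "Broca": (3, 4, 13, 14),
    "FPA": (5, 6, 15, 16),
    "OA": (7, 8, 17, 18),
    "FEF": (9, 11, 19, 20),
    "SMA": (31, 32, 21, 22),
    "PMC": (33, 34, 23, 24),
    "PSC": (35, 36, 25, 26),
    "STG": (37, 38, 27, 28),
    "Wernicke": (39, 40, 29, 30),
}


@dataclass(frozen=True)
class Channel:
    """One source-detector measurement channel."""

    channel_id: int
    source_id: int
    detector_id: int
    separation_cm: float
    hemisphere: str  # "left" or "right"
    roi: str


@dataclass(frozen=True)
class ProbeLayout:
    """Full montage description shared by every analysis stage."""

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    n_sources: int = 16
    n_detectors: int = 16

    def __post_init__(self) -> None:
        if len(self.channels) != 40:
            raise ValueError(f"layout must define 40 channels, got {len(self.channels)}")
        ids = [c.channel_id for c in self.channels]
        if ids != list(range(1, 41)):
            raise ValueError("channels must be ordered CH1..CH40 with unique ids")
        left = {c.channel_id for c in self.channels if c.hemisphere == "left"}
        right = {c.channel_id for c in self.channels if c.hemisphere == "right"}
        if len(left) != 20 or len(right) != 20:
            raise ValueError(
                f"hemisphere partition must be 20/20, got {len(left)}/{len(right)}"
            )
        for c in self.channels:
            if c.roi not in ROI_LABELS:
                raise ValueError(f"CH{c.channel_id}: unknown ROI {c.roi!r}")
            if c.separation_cm <= 0:
                raise ValueError(f"CH{c.channel_id}: nonpositive separation")
            if c.hemisphere not in ("left", "right"):
                raise ValueError(f"CH{c.channel_id}: bad hemisphere {c.hemisphere!r}")
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths required")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def separations_cm(self) -> np.ndarray:
        return np.array([c.separation_cm for c in self.channels])

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        """0-based indices of channels in one hemisphere."""
        return np.array(
            [i for i, c in enumerate(self.channels) if c.hemisphere == hemisphere],
            dtype=int,
        )

    def roi_indices(self, roi: str) -> np.ndarray:
        """0-based indices of channels assigned to one ROI."""
        idx = np.array([i for i, c in enumerate(self.channels) if c.roi == roi], dtype=int)
        if idx.size == 0:
            raise ValueError(f"ROI {roi!r} has no channels in this layout")
        return idx

    def region_indices(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        """0-based indices of channels in the prefrontal or motor region,
        optionally restricted to one hemisphere."""
        rois = {"prefrontal": PREFRONTAL_ROIS, "motor": MOTOR_ROIS}.get(region)
        if rois is None:
            raise ValueError(f"unknown region {region!r}")
        idx = [
            i
            for i, c in enumerate(self.channels)
            if c.roi in rois and (hemisphere is None or c.hemisphere == hemisphere)
        ]
        if not idx:
            raise ValueError(f"no channels for region {region!r}/{hemisphere!r}")
        return np.array(idx, dtype=int)

    def roi_map(self) -> dict[int, str]:
        return {c.channel_id: c.roi for c in self.channels}


def default_layout(roi_blocks: dict[str, Sequence[int]] | None = None) -> ProbeLayout:
    """Build the standard 40-channel layout.

    Parameters
    ----------
    roi_blocks
        Optional channel->ROI override, a map from ROI label to the 1-based
        channel ids it covers.  Defaults to :data:`DEFAULT_ROI_BLOCKS`.
    """
    blocks = roi_blocks if roi_blocks is not None else DEFAULT_ROI_BLOCKS
    roi_of: dict[int, str] = {}
    for roi, chans in blocks.items():
        for ch in chans:
            if ch in roi_of:
                raise ValueError(f"CH{ch} assigned to two ROIs")
            roi_of[ch] = roi
    if set(roi_of) != set(range(1, 41)):
        missing = sorted(set(range(1, 41)) - set(roi_of))
        raise ValueError(f"ROI map must cover CH1..CH40; missing {missing}")
    channels = tuple(
        Channel(
            channel_id=ch,
            source_id=(ch - 1) % 16 + 1,
            detector_id=(ch - 1) // 3 + 1,
            separation_cm=2.5,
            hemisphere="left" if ch in LEFT_CHANNEL_IDS else "right",
            roi=roi_of[ch],
        )
        for ch in range(1, 41)
    )
    return ProbeLayout(channels=channels)


@dataclass(frozen=True)
class TaskParadigm:
    """Block-design timing: pre-rest, four task blocks, post-rest.

    Defaults encode a 30 s pre-task rest, a 60 s task split into four
    sequential 15 s blocks, and a 60 s post-task rest at 5 Hz, i.e. 750
    samples.  All windows are half-open 0-based sample ranges.
    """

    pre_rest_s: float = 30.0
    block_duration_s: float = 15.0
    n_blocks: int = 4
    post_rest_s: float = 60.0
    fs: float = 5.0

    def __post_init__(self) -> None:
        if min(self.pre_rest_s, self.block_duration_s, self.post_rest_s) < 0:
            raise ValueError("durations must be nonnegative")
        if self.n_blocks < 1 or self.fs <= 0:
            raise ValueError("need at least one block and positive sampling rate")

    @property
    def task_duration_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.pre_rest_s + self.task_duration_s + self.post_rest_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.fs))

    @property
    def task_window(self) -> tuple[int, int]:
        """Half-open [start, stop) sample range of the task period."""
        start = int(round(self.pre_rest_s * self.fs))
        stop = start + int(round(self.task_duration_s * self.fs))
        return start, stop

    @property
    def baseline_window(self) -> tuple[int, int]:
        """The pre-task rest, used as the optical-density baseline."""
        return 0, int(round(self.pre_rest_s * self.fs))

    @property
    def block_onsets_samples(self) -> np.ndarray:
        start = int(round(self.pre_rest_s * self.fs))
        step = int(round(self.block_duration_s * self.fs))
        return start + step * np.arange(self.n_blocks)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class RawRecording:
    """Per-subject raw optical intensities.

    intensity has shape (n_channels, n_wavelengths, n_samples) in arbitrary
    detector units and must be strictly positive; events are 0-based sample
    indices of task-block onsets.
    """

    subject_id: str
    group: str
    intensity: np.ndarray
    fs: float
    events: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.events = np.asarray(self.events, dtype=int)

    def validate(self, layout: ProbeLayout, paradigm: TaskParadigm | None = None) -> "RawRecording":
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, time)")
        nc, nw, _ = self.intensity.shape
        if nc != layout.n_channels:
            raise ValueError(
                f"channel count mismatch: file has {nc}, layout expects {layout.n_channels}"
            )
        if nw != len(layout.wavelengths_nm):
            raise ValueError(f"wavelength count mismatch: {nw}")
        bad = np.argwhere(~(self.intensity > 0) | ~np.isfinite(self.intensity))
        if bad.size:
            ch, wl, t = bad[0]
            raise ValueError(
                f"nonpositive or nonfinite intensity at CH{ch + 1}, "
                f"wavelength index {wl}, sample {t}"
            )
        if paradigm is not None:
            if abs(self.fs - paradigm.fs) > 1e-9:
                raise ValueError(f"sampling rate {self.fs} Hz != paradigm {paradigm.fs} Hz")
            if self.intensity.shape[2] != paradigm.n_samples:
                raise ValueError(
                    f"recording has {self.intensity.shape[2]} samples, paradigm "
                    f"requires {paradigm.n_samples}"
                )
        return self


def extract_task_window(series: np.ndarray, paradigm: TaskParadigm, axis: int = -1) -> np.ndarray:
    """Slice out the task-period samples (half-open window).

    Accepts either a full-paradigm series (returns the task window) or a
    series already of task-window length (returned unchanged, making the
    operation idempotent); any other length is rejected.
    """
    series = np.asarray(series)
    n = series.shape[axis]
    start, stop = paradigm.task_window
    if n == stop - start:
        return series
    if n < paradigm.n_samples:
        raise ValueError(
            f"series has {n} samples along axis {axis}; paradigm requires "
            f"{paradigm.n_samples} (or exactly the {stop - start}-sample task window)"
        )
    idx = [slice(None)] * series.ndim
    idx[axis] = slice(start, stop)
    return series[tuple(idx)]


def signal_validity(
    rec: RawRecording,
    window: int = 25,
    cv_max: float = 0.1,
) -> tuple[np.ndarray, list[int]]:
    """Per-channel fraction of valid signal windows, NIRStar-style.

    The recording is cut into non-overlapping windows of ``window`` samples;
    a window is valid when all its values are finite and positive and its
    coefficient of variation (sd/mean) is at most ``cv_max``, for every
    wavelength.  Returns the validity fraction per channel and the 1-based
    ids of channels below the 0.9 acceptance level.
    """
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    x = rec.intensity
    if x.size == 0:
        raise ValueError("empty recording")
    for ch in range(x.shape[0]):
        if not np.any(x[ch] > 0):
            raise ValueError(f"CH{ch + 1}: no positive samples (nonpositive trace)")
    n_win = x.shape[2] // window
    if n_win == 0:
        raise ValueError("recording shorter than one validity window")
    w = x[:, :, : n_win * window].reshape(x.shape[0], x.shape[1], n_win, window)
    finite_pos = np.all(np.isfinite(w) & (w > 0), axis=3)
    mean = w.mean(axis=3)
    sd = w.std(axis=3, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    valid = finite_pos & (cv <= cv_max)
    validity = valid.all(axis=1).mean(axis=1)  # both wavelengths must pass
    flagged = [i + 1 for i in range(x.shape[0]) if validity[i] < 0.9]
    return validity, flagged
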