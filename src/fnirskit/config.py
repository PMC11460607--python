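"""Analysis configuration: DPFs, extinction coefficients, filters, thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

#: Molar extinction coefficients eps(lambda, species) in cm^-1 (mol/L)^-1,
#: rows = (760 nm, 850 nm), columns = (HbO2, Hb).  Compiled in vivo values
#: (Prahl's tabulation of hemoglobin spectra), the de facto standard in
#: continuous-wave NIRS processing software.
EXTINCTION_760_850 = np.array(
    [
        [586.0, 1548.52],
        [1058.0, 691.32],
    ]
)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the processing chain.

    dpf
        Differential pathlength factors per wavelength, (760 nm, 850 nm).
        Defaults to (6, 5): DPF decreases with wavelength in adult head
        tissue, so the larger value is assigned to 760 nm.
    extinction
        2x2 molar extinction matrix, rows = wavelengths, cols = (HbO2, Hb),
        in cm^-1 (mol/L)^-1.
    band_hz
        Band-pass edges for hemodynamic analysis, default (0.01, 0.1) Hz.
    filter_order
        Butterworth order (applied zero-phase, forward-backward).
    spline_window_s, spline_threshold, spline_degree
        Motion-artifact detection window (s), the moving-sd multiple that
        flags an artifact segment, and the correction-spline degree.
    fdr_alpha
        Benjamini-Hochberg level for all channel/pair families.
    li_threshold
        |LI| at or beyond which a subject is lateralized (0.1).
    li_floor_umol
        |L + R| below which the laterality index is recorded as undefined.
    """

    dpf: tuple[float, float] = (6.0, 5.0)
    extinction: np.ndarray = field(default_factory=lambda: EXTINCTION_760_850.copy())
    band_hz: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 3
    spline_window_s: float = 2.0
    spline_threshold: float = 3.0
    spline_degree: int = 3
    fdr_alpha: float = 0.05
    li_threshold: float = 0.1
    li_floor_umol: float = 1e-3
    prewhiten: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.dpf = tuple(float(v) for v in self.dpf)
        self.band_hz = tuple(float(v) for v in self.band_hz)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelength x species)")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPFs must be positive")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")

    def validate_band(self, fs: float) -> None:
        if self.band_hz[1] >= fs / 2:
            raise ValueError(f"band upper edge {self.band_hz[1]} >= Nyquist {fs / 2}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["extinction"] = self.extinction.tolist()
        d["dpf"] = list(self.dpf)
        d["band_hz"] = list(self.band_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "extinction" in d:
            d["extinction"] = np.asarray(d["extinction"], dtype=float)
        for key in ("dpf", "band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
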