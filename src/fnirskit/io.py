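"""File I/O: SNIRF (HDF5) and a long-format CSV dialect for raw recordings.

The SNIRF writer emits the subset of the SNIRF 1.0 layout needed for
continuous-wave intensity data: /nirs/data1/dataTimeSeries (+time), one
measurementList entry per channel x wavelength, probe wavelengths, and a
stimulus table carrying the task-block onsets.  The CSV dialect is tidy
long format with columns (subject_id, group, channel, wavelength_nm,
sample_index, intensity), UTF-8, header required.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .probe import ProbeLayout, RawRecording, TaskParadigm
from .synth import SyntheticTruth

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["subject_id", "group", "channel", "wavelength_nm", "sample_index", "intensity"]


def _str_dataset(grp: h5py.Group, name: str, value: str) -> None:
    grp.create_dataset(name, data=np.bytes_(value))


def write_snirf(
    path: str | Path,
    rec: RawRecording,
    layout: ProbeLayout,
    paradigm: TaskParadigm | None = None,
) -> None:
    """Write a recording as a minimal SNIRF 1.0 file."""
    nch, nwl, n = rec.intensity.shape
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", rec.subject_id)
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "cm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        _str_dataset(meta, "Group", rec.group)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(layout.wavelengths_nm, float))
        pos = np.zeros((max(layout.n_sources, layout.n_detectors), 3))
        probe.create_dataset("sourcePos3D", data=pos[: layout.n_sources])
        probe.create_dataset("detectorPos3D", data=pos[: layout.n_detectors])
        data = nirs.create_group("data1")
        # time-major matrix, channel-fast ordering: column = ch * nwl + wl
        dts = rec.intensity.reshape(nch * nwl, n).T
        data.create_dataset("dataTimeSeries", data=dts)
        data.create_dataset("time", data=np.arange(n) / rec.fs)
        for ch in range(nch):
            for wl in range(nwl):
                ml = data.create_group(f"measurementList{ch * nwl + wl + 1}")
                ml.create_dataset("sourceIndex", data=layout.channels[ch].source_id)
                ml.create_dataset("detectorIndex", data=layout.channels[ch].detector_id)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        if paradigm is not None:
            stim = nirs.create_group("stim1")
            _str_dataset(stim, "name", "task")
            onsets = paradigm.block_onsets_samples / paradigm.fs
            rows = np.column_stack(
                [onsets, np.full(paradigm.n_blocks, paradigm.block_duration_s),
                 np.ones(paradigm.n_blocks)]
            )
            stim.create_dataset("data", data=rows)


def read_snirf(path: str | Path, layout: ProbeLayout,
               paradigm: TaskParadigm | None = None) -> RawRecording:
    """Read a recording written by :func:`write_snirf` (SNIRF 1.0 subset)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        dts = np.asarray(nirs["data1/dataTimeSeries"])
        time = np.asarray(nirs["data1/time"])
        if time.size < 2:
            raise ValueError("time vector too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        nwl = len(layout.wavelengths_nm)
        if dts.shape[1] % nwl:
            raise ValueError("column count is not a multiple of the wavelength count")
        nch = dts.shape[1] // nwl
        if nch != layout.n_channels:
            raise ValueError(
                f"channel count mismatch: file has {nch}, layout expects {layout.n_channels}"
            )
        intensity = dts.T.reshape(nch, nwl, -1)
        meta = nirs["metaDataTags"]
        subject_id = meta["SubjectID"][()].decode()
        group = meta["Group"][()].decode() if "Group" in meta else "HEALTHY"
        events = np.array([], dtype=int)
        if "stim1" in nirs:
            onsets_s = np.asarray(nirs["stim1/data"])[:, 0]
            events = np.round(onsets_s * fs).astype(int)
    if paradigm is not None:
        expected = paradigm.block_onsets_samples
        if events.size and not np.array_equal(np.sort(events), expected):
            logger.warning(
                "in-file stimulus onsets %s conflict with paradigm %s; paradigm wins",
                events.tolist(), expected.tolist(),
            )
        events = expected
    rec = RawRecording(subject_id=subject_id, group=group, intensity=intensity,
                       fs=fs, events=events)
    return rec.validate(layout, paradigm)


def write_csv(path: str | Path, rec: RawRecording, layout: ProbeLayout) -> None:
    """Write a recording in the tidy long-format CSV dialect."""
    nch, nwl, n = rec.intensity.shape
    ch, wl, idx = np.meshgrid(
        np.arange(1, nch + 1), np.asarray(layout.wavelengths_nm), np.arange(n),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "channel": ch.ravel(),
            "wavelength_nm": wl.ravel(),
            "sample_index": idx.ravel(),
            "intensity": rec.intensity.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_csv(path: str | Path, layout: ProbeLayout,
             paradigm: TaskParadigm | None = None) -> RawRecording:
    """Read the long-format CSV dialect back into a RawRecording."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing required columns: {missing}")
    channels = np.sort(df["channel"].unique())
    if len(channels) != layout.n_channels:
        raise ValueError(
            f"channel count mismatch: file has {len(channels)}, "
            f"layout expects {layout.n_channels}"
        )
    bad = df[~(df["intensity"] > 0) | ~np.isfinite(df["intensity"])]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"nonpositive intensity at CH{int(row['channel'])}, "
            f"wavelength {row['wavelength_nm']} nm, sample {int(row['sample_index'])}"
        )
    wls = list(layout.wavelengths_nm)
    n = int(df["sample_index"].max()) + 1
    intensity = np.empty((layout.n_channels, len(wls), n))
    pivot = df.pivot_table(index=["channel", "wavelength_nm"], columns="sample_index",
                           values="intensity")
    for i in range(layout.n_channels):
        for j, wl in enumerate(wls):
            intensity[i, j] = pivot.loc[(i + 1, wl)].to_numpy()
    fs = paradigm.fs if paradigm is not None else 5.0
    events = paradigm.block_onsets_samples if paradigm is not None else np.array([], int)
    rec = RawRecording(
        subject_id=str(df["subject_id"].iloc[0]), group=str(df["group"].iloc[0]),
        intensity=intensity, fs=fs, events=events,
    )
    return rec.validate(layout, paradigm)


def load_recording(path: str | Path, layout: ProbeLayout,
                   paradigm: TaskParadigm | None = None) -> RawRecording:
    """Load a recording, dispatching on file extension (.snirf/.h5 or .csv)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".snirf", ".h5", ".hdf5"):
        return read_snirf(path, layout, paradigm)
    if suffix == ".csv":
        return read_csv(path, layout, paradigm)
    raise ValueError(f"unsupported recording format {suffix!r}")


def write_truth_csv(path: str | Path, truth: SyntheticTruth) -> None:
    """Ground-truth sidecar: per subject x channel true beta (long CSV)."""
    truth.beta_table().to_csv(path, index=False)
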