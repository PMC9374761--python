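"""Readers and writers for the pipeline's on-disk formats.

Every signal type has a plain columnar text format (CSV/TSV with header)
so the repository has no binary-format hard dependency:

* recording:  CSV ``time_s, eeg1, ..., emg``
* hypnogram:  TSV ``epoch_index, onset_s, state``
* traces:     CSV ``time_s, cell_0001, ...``
* schedule:   TSV ``onset_s, offset_s, kind``
* events:     CSV ``cell_id, time_s, magnitude``

EDF recordings are read through :mod:`mne` when that package is present.
All writers use a fixed float format so identical data give byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import STATES, CellTraces, EventTrain, Hypnogram, Recording
from .errors import DataError

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a columnar CSV (time_s, eeg1..eegK, emg)."""
    data = {"time_s": rec.times_s}
    for i, ch in enumerate(rec.eeg):
        data[f"eeg{i + 1}"] = ch
    data["emg"] = rec.emg
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def _read_recording_csv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # malformed file
        raise DataError(f"cannot parse recording {path}: {e}") from e
    eeg_cols = sorted(c for c in df.columns if c.lower().startswith("eeg"))
    if "time_s" not in df.columns or not eeg_cols or "emg" not in df.columns:
        raise DataError(
            f"{path}: expected columns time_s, eeg1.., emg; got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise DataError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    eeg = np.stack([df[c].to_numpy(float) for c in eeg_cols])
    return Recording(eeg, df["emg"].to_numpy(float), fs)


def _read_recording_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as e:  # pragma: no cover - environment-dependent
        raise DataError("EDF support requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = {n.upper(): n for n in raw.ch_names}
    eeg_names = sorted(n for n in names if n.startswith("EEG"))
    if not eeg_names or "EMG" not in names:
        raise DataError(f"{path}: EDF must contain EEG* and EMG channels")
    eeg = np.stack([raw.get_data(picks=[names[n]])[0] for n in eeg_names]) * 1e6
    emg = raw.get_data(picks=[names["EMG"]])[0] * 1e6
    return Recording(eeg, emg, float(raw.info["sfreq"]))


def read_recording(path: str | Path, fmt: str = "auto") -> Recording:
    """Read a recording from columnar CSV or EDF (by extension in auto mode)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "columnar"
    if fmt == "edf":
        return _read_recording_edf(path)
    if fmt == "columnar":
        return _read_recording_csv(path)
    raise DataError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# hypnograms

def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    hyp.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_hypnogram(path: str | Path, provenance: str = "auto") -> Hypnogram:
    """Read a hypnogram TSV; rejects unknown labels and epoch gaps/overlaps."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"state": str})
    except Exception as e:
        raise DataError(f"cannot parse hypnogram {path}: {e}") from e
    required = {"epoch_index", "onset_s", "state"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: hypnogram TSV needs columns {sorted(required)}")
    if len(df) == 0:
        return Hypnogram(np.empty(0, dtype="U1"), provenance=provenance)
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise DataError(f"{path}: unknown state labels {sorted(bad)}")
    onsets = df["onset_s"].to_numpy(float)
    if len(onsets) > 1:
        steps = np.diff(onsets)
        epoch_s = float(steps[0])
        if np.any(np.abs(steps - epoch_s) > 1e-9):
            raise DataError(f"{path}: epochs have gaps or overlaps")
    else:
        epoch_s = 2.0
    return Hypnogram(df["state"].to_numpy(), epoch_s=epoch_s, provenance=provenance)


# ---------------------------------------------------------------------------
# calcium traces / events

def write_traces(traces: CellTraces, path: str | Path) -> None:
    traces.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_traces(path: str | Path) -> CellTraces:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise DataError(f"cannot parse traces {path}: {e}") from e
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise DataError(f"{path}: expected columns time_s, cell_*")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least two frames")
    fs = 1.0 / float(np.median(np.diff(t)))
    cells = [c for c in df.columns if c != "time_s"]
    return CellTraces(np.stack([df[c].to_numpy(float) for c in cells]), fs, cells)


def write_events(trains: list[EventTrain], path: str | Path) -> None:
    rows = []
    for tr in trains:
        for t, m in zip(tr.times_s, tr.magnitudes):
            rows.append({"cell_id": tr.cell_id, "time_s": t, "magnitude": m})
    pd.DataFrame(rows, columns=["cell_id", "time_s", "magnitude"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_events(path: str | Path) -> list[EventTrain]:
    df = pd.read_csv(path)
    return [
        EventTrain(g["time_s"].to_numpy(float), g["magnitude"].to_numpy(float), cid)
        for cid, g in df.groupby("cell_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# schedules

def write_schedule(schedule: pd.DataFrame, path: str | Path) -> None:
    schedule.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_schedule(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:
        raise DataError(f"cannot parse schedule {path}: {e}") from e
    if not {"onset_s", "offset_s"}.issubset(df.columns):
        raise DataError(f"{path}: schedule TSV needs onset_s and offset_s")
    if np.any(df["offset_s"].to_numpy() <= df["onset_s"].to_numpy()):
        raise DataError(f"{path}: schedule has offset <= onset")
    return df
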