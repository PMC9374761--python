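"""Shared containers for the pipeline.

Time convention everywhere: seconds from session start, half-open intervals
``[onset, offset)``, 0-based epoch indices.  Vigilance states are the
three-letter alphabet ``W`` (wake), ``N`` (NREM sleep), ``R`` (REM sleep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical state order used throughout (indices 0, 1, 2).
STATES: tuple[str, ...] = ("W", "N", "R")

STATE_TO_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels at a fixed epoch length.

    Parameters
    ----------
    states
        One label per epoch, each in ``{"W", "N", "R"}``.
    epoch_s
        Epoch length in seconds (default 2 s).
    provenance
        One of ``{"auto", "manual-corrected", "simulated"}``.
    """

    states: np.ndarray
    epoch_s: float = 2.0
    provenance: str = "auto"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U1")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise DataError(f"unknown state labels: {sorted(bad)}")
        if self.epoch_s <= 0:
            raise DataError("epoch_s must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def onsets_s(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_s

    def epoch_index(self, t_s: float | np.ndarray) -> np.ndarray:
        """Index of the epoch containing time ``t`` ([onset, onset+epoch_s))."""
        return np.floor(np.asarray(t_s, dtype=float) / self.epoch_s).astype(int)

    def state_at(self, t_s: float | np.ndarray) -> np.ndarray:
        idx = self.epoch_index(t_s)
        if np.any(idx < 0) or np.any(idx >= self.n_epochs):
            raise DataError("time outside hypnogram span")
        return self.states[idx]

    def state_seconds(self) -> dict[str, float]:
        """Total time spent in each state, seconds."""
        return {s: float(np.sum(self.states == s)) * self.epoch_s for s in STATES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "onset_s": self.onsets_s,
                "state": self.states,
            }
        )


@dataclass
class Recording:
    """Multichannel EEG/EMG recording.

    ``eeg`` is (n_channels, n_samples) in µV; ``emg`` is (n_samples,) in µV.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.emg = np.asarray(self.emg, dtype=float)
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if self.eeg.shape[1] != self.emg.size:
            raise DataError("EEG and EMG channel lengths differ")

    @property
    def n_samples(self) -> int:
        return int(self.emg.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def bouts_to_frame(records: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Build a bout table from (state, onset_s, offset_s) records."""
    df = pd.DataFrame(records, columns=["state", "onset_s", "offset_s"])
    df["duration_s"] = df["offset_s"] - df["onset_s"]
    return df


@dataclass
class EventTrain:
    """Discrete calcium events for one cell: sorted times and magnitudes."""

    times_s: np.ndarray
    magnitudes: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.times_s.shape != self.magnitudes.shape:
            raise DataError("times and magnitudes must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            order = np.argsort(self.times_s, kind="stable")
            self.times_s = self.times_s[order]
            self.magnitudes = self.magnitudes[order]
        if np.any(self.magnitudes < 0):
            raise DataError("event magnitudes must be nonnegative")

    @property
    def n_events(self) -> int:
        return int(self.times_s.size)

    @property
    def total_magnitude(self) -> float:
        return float(self.magnitudes.sum())


@dataclass
class CellTraces:
    """Fluorescence traces for a population of ROIs at a common frame rate."""

    traces: np.ndarray  # (n_cells, n_frames)
    fs: float
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i + 1:04d}" for i in range(self.traces.shape[0])]
        if len(self.cell_ids) != self.traces.shape[0]:
            raise DataError("cell_ids length does not match trace count")

    @property
    def n_cells(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[1])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times_s}
        for cid, tr in zip(self.cell_ids, self.traces):
            data[cid] = tr
        return pd.DataFrame(data)


@dataclass
class PhotometrySession:
    """Dual-channel fiber-photometry session (465 nm signal, 405 nm isosbestic)."""

    f465: np.ndarray
    f405: np.ndarray
    fs: float
    stim_onsets_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if self.f465.shape != self.f405.shape:
            raise DataError("photometry channels must have equal length")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.f465.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Sweep:
    """One patch-clamp sweep with its stimulation onset marker."""

    samples: np.ndarray  # mV (potentials) or pA (currents)
    fs: float
    stim_onset_s: float
    polarity: str = "depolarizing"  # or "inward-current"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.polarity not in ("depolarizing", "inward-current"):
            raise DataError(f"unknown polarity {self.polarity!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
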