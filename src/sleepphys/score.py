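"""EEG/EMG vigilance-state scoring.

The scoring chain: a sliding-window FFT spectrogram (5-s Hann window
stepped by 2-s epochs), per-epoch band-power features (delta 0.5-4 Hz,
theta 6-9 Hz, total 0.5-25 Hz) plus EMG RMS, a three-way decision rule
(high EMG -> wake; high theta/delta among the rest -> REM; remainder ->
NREM) with light post-smoothing, run-length bout segmentation, and
relative delta power (per-epoch delta divided by the session-mean total
power).

The rule-based classifier is a documented stand-in for semi-automatic
scoring: thresholds are either supplied or estimated from the data, and a
sparse manual-override list can correct individual epochs afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .core import Hypnogram, Recording, bouts_to_frame
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ThresholdEstimationError,
)

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 9.0)
TOTAL_BAND = (0.5, 25.0)
EMG_BAND = (10.0, 100.0)


@dataclass
class Spectrogram:
    """Per-epoch one-sided power spectra in µV²/Hz."""

    epoch_times: np.ndarray  # epoch onsets, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_epochs, n_freqs), >= 0
    window_s: float = 5.0
    step_s: float = 2.0

    @property
    def n_epochs(self) -> int:
        return int(self.power.shape[0])

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_power(self, band: tuple[float, float]) -> np.ndarray:
        """Integrated power over ``band`` (inclusive edges), per epoch."""
        lo, hi = band
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        return self.power[:, mask].sum(axis=1) * self.df


def compute_spectrogram(
    rec: Recording,
    window_s: float = 5.0,
    step_s: float = 2.0,
    channel: int = 0,
) -> Spectrogram:
    """Sliding-window FFT spectrogram of one EEG channel.

    Each 2-s epoch gets the Hann-tapered periodogram of the 5-s window
    left-aligned to its onset; trailing partial windows are dropped, so the
    epoch count is ``floor((duration - window) / step) + 1``.  Power is
    one-sided density (µV²/Hz): integrating over frequency recovers the
    (windowed) signal variance.
    """
    x = rec.eeg[channel]
    fs = rec.fs
    nwin = int(round(window_s * fs))
    hop = int(round(step_s * fs))
    if x.size < nwin:
        raise InsufficientDataError(
            f"recording ({x.size / fs:.1f} s) shorter than one {window_s} s window"
        )
    win = np.hanning(nwin)
    scale = 2.0 / (fs * np.sum(win**2))
    segs = sliding_window_view(x, nwin)[::hop]
    spec = np.fft.rfft(segs * win, axis=1)
    power = scale * np.abs(spec) ** 2
    power[:, 0] /= 2.0
    if nwin % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    epoch_times = np.arange(segs.shape[0]) * step_s
    return Spectrogram(epoch_times, freqs, power, window_s, step_s)


def extract_features(
    spec: Spectrogram,
    rec: Recording,
    delta_band: tuple[float, float] = DELTA_BAND,
    theta_band: tuple[float, float] = THETA_BAND,
    total_band: tuple[float, float] = TOTAL_BAND,
    emg_band: tuple[float, float] | None = EMG_BAND,
) -> pd.DataFrame:
    """Per-epoch scoring features: band powers, theta/delta ratio, EMG RMS.

    EMG is band-passed to ``emg_band`` (10-100 Hz default; ``None`` skips
    filtering) and summarized as RMS over each 2-s epoch.  The ratio is
    NaN (flagged in ``ratio_defined``) where delta power is zero.
    """
    delta = spec.band_power(delta_band)
    theta = spec.band_power(theta_band)
    total = spec.band_power(total_band)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.where(delta > 0, delta, 1.0), np.nan)

    emg = rec.emg
    if emg_band is not None:
        nyq = rec.fs / 2
        hi = min(emg_band[1], 0.95 * nyq)
        sos = signal.butter(4, [emg_band[0] / nyq, hi / nyq], "bandpass", output="sos")
        emg = signal.sosfiltfilt(sos, emg)
    spe = int(round(spec.step_s * rec.fs))
    emg_rms = np.empty(spec.n_epochs)
    for i in range(spec.n_epochs):
        seg = emg[i * spe : (i + 1) * spe]
        emg_rms[i] = np.sqrt(np.mean(seg**2))

    return pd.DataFrame(
        {
            "epoch_time_s": spec.epoch_times,
            "delta_power": delta,
            "theta_power": theta,
            "theta_delta_ratio": ratio,
            "ratio_defined": delta > 0,
            "total_power": total,
            "emg_rms": emg_rms,
        }
    )


@dataclass
class Thresholds:
    """Decision thresholds for the three-state rule."""

    emg_rms: float
    theta_delta: float = 1.0


def estimate_emg_threshold(emg_rms: np.ndarray) -> float:
    """Two-component split of log EMG RMS.

    A deterministic 1-D 2-means in log space, initialised at the 10th and
    90th percentiles, whose midpoint separates the high-tone (wake) and
    low-tone (sleep) clusters.  Raises on degenerate (near-constant)
    features.
    """
    x = np.log(np.asarray(emg_rms, dtype=float) + 1e-300)
    if not np.all(np.isfinite(x)):
        raise ThresholdEstimationError("EMG RMS contains non-finite or zero values")
    lo, hi = np.percentile(x, [10, 90])
    if hi - lo < 1e-6:
        raise ThresholdEstimationError(
            "EMG RMS nearly constant; supply an explicit threshold"
        )
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        if assign.all() or not assign.any():
            raise ThresholdEstimationError(
                "EMG RMS does not separate into two components"
            )
        new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
        if np.allclose(new, c):
            break
        c = new
    return float(np.exp(c.mean()))


def classify_epochs(
    features: pd.DataFrame,
    thresholds: Thresholds | None = None,
    smooth_islands: bool = True,
    enforce_wake_to_rem: bool = True,
    overrides: list[tuple[int, str]] | None = None,
) -> Hypnogram:
    """Score epochs into W/N/R with the EMG-first decision rule.

    Epochs with EMG RMS above threshold are wake; among the rest, epochs
    with theta/delta ratio above threshold are REM and the remainder NREM.
    Post-smoothing relabels single-epoch islands to their surrounding state
    and forbids REM directly after wake (standard rodent constraint); both
    are toggleable.  ``overrides`` is a sparse list of (epoch, state)
    manual corrections applied last.
    """
    if thresholds is None:
        thresholds = Thresholds(emg_rms=estimate_emg_threshold(features["emg_rms"].to_numpy()))
    emg = features["emg_rms"].to_numpy()
    ratio = features["theta_delta_ratio"].to_numpy()
    ratio = np.where(np.isnan(ratio), np.inf, ratio)  # zero delta reads as theta-dominant

    states = np.where(
        emg > thresholds.emg_rms,
        "W",
        np.where(ratio > thresholds.theta_delta, "R", "N"),
    ).astype("U1")

    if smooth_islands and states.size >= 3:
        inner = (states[1:-1] != states[:-2]) & (states[:-2] == states[2:])
        idx = np.flatnonzero(inner) + 1
        states[idx] = states[idx - 1]
    if enforce_wake_to_rem:
        for i in range(1, states.size):
            if states[i] == "R" and states[i - 1] == "W":
                states[i] = "W"

    provenance = "auto"
    if overrides:
        for i, s in overrides:
            states[i] = s
        provenance = "manual-corrected"
    step = float(np.diff(features["epoch_time_s"].to_numpy()[:2])[0]) if len(features) > 1 else 2.0
    return Hypnogram(states, epoch_s=step, provenance=provenance)


def segment_bouts(hyp: Hypnogram, min_bout_s: float = 0.0) -> pd.DataFrame:
    """Run-length segmentation of a hypnogram into bouts.

    Maximal runs of identical labels become bouts; runs shorter than
    ``min_bout_s`` are absorbed into the preceding bout (or the following
    one at the session start), and adjacent same-state bouts re-merged, so
    the table always tiles the session exactly.
    """
    states = hyp.states
    if states.size == 0:
        return bouts_to_frame([])
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, states.size]
    runs = [[states[s], s, e] for s, e in zip(starts, ends)]

    if min_bout_s > 0:
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, run in enumerate(runs):
                if (run[2] - run[1]) * hyp.epoch_s < min_bout_s:
                    j = i - 1 if i > 0 else i + 1
                    if j < i:
                        runs[j][2] = run[2]
                    else:
                        runs[j][1] = run[1]
                    del runs[i]
                    # re-merge neighbours that now touch with equal state
                    k = 1
                    while k < len(runs):
                        if runs[k][0] == runs[k - 1][0]:
                            runs[k - 1][2] = runs[k][2]
                            del runs[k]
                        else:
                            k += 1
                    changed = True
                    break

    return bouts_to_frame(
        [(r[0], r[1] * hyp.epoch_s, r[2] * hyp.epoch_s) for r in runs]
    )


def relative_delta(
    spec: Spectrogram,
    delta_band: tuple[float, float] = DELTA_BAND,
    total_band: tuple[float, float] = TOTAL_BAND,
) -> np.ndarray:
    """Relative delta power: per-epoch delta over session-mean total power.

    Dividing by the session mean (not the per-epoch total) keeps the
    measure comparable across epochs within a session and makes it exactly
    invariant to global amplitude rescaling.
    """
    delta = spec.band_power(delta_band)
    total = spec.band_power(total_band)
    mean_total = float(total.mean())
    if mean_total <= 0:
        raise DegenerateDataError("session mean total power is zero")
    return delta / mean_total
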