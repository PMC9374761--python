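"""Fiber-photometry correction and normalization.

The standard isosbestic chain: low-pass both channels at 2 Hz, fit the
405 nm (calcium-independent) channel to the 465 nm channel by least
squares, take DF/F = (F - F0)/F0 with F0 the fitted 405 signal, smooth
with a moving average, downsample to 5 Hz, and optionally z-score for
across-animal normalization.  Shared motion and bleaching artifacts live
in both channels and cancel in the fit; the calcium transient lives only
in the 465 nm channel and survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .core import PhotometrySession
from .errors import DataError, DegenerateDataError, InsufficientDataError
from .statsutil import bootstrap_ci


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float = 2.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    sos = signal.butter(4, cutoff_hz / (fs / 2), "lowpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def smooth_downsample(
    x: np.ndarray,
    fs: float,
    out_fs: float = 5.0,
    window_s: float | None = None,
) -> np.ndarray:
    """Moving-average smoothing followed by decimation to ``out_fs``.

    Default window is one output period (200 ms at 5 Hz).  A constant
    input maps to the same constant; output length is
    ``floor(n * out_fs / fs)`` within one sample.
    """
    if fs < out_fs:
        raise DataError(f"cannot downsample {fs} Hz to {out_fs} Hz")
    x = np.asarray(x, dtype=float)
    if window_s is None:
        window_s = 1.0 / out_fs
    w = max(1, int(round(window_s * fs)))
    sm = uniform_filter1d(x, size=w, mode="nearest")
    n_out = int(np.floor(x.size * out_fs / fs))
    idx = np.minimum((np.arange(n_out) * fs / out_fs).round().astype(int), x.size - 1)
    return sm[idx]


def zscore_trace(x: np.ndarray) -> np.ndarray:
    """Z-score a trace; errors on zero-variance input."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateDataError("trace is constant; z-score undefined")
    return (x - x.mean()) / sd


@dataclass
class CorrectedTrace:
    """Output of the isosbestic correction chain."""

    dff: np.ndarray  # at fs_out
    fs_out: float
    fit_gain: float
    fit_offset: float
    zscored: np.ndarray | None = None


def correct_isosbestic(
    sess: PhotometrySession,
    lowpass_hz: float = 2.0,
    fit_offset: bool = True,
    out_fs: float = 5.0,
    smooth_window_s: float | None = None,
    zscore: bool = False,
) -> CorrectedTrace:
    """Isosbestic-corrected DF/F at 5 Hz.

    Both channels are low-passed at ``lowpass_hz``; (gain, offset) minimize
    the squared error of ``gain * f405 + offset`` against f465 (gain-only
    with ``fit_offset=False``); DF/F is (f465 - F0)/F0 with F0 the fitted
    signal, then smoothed and downsampled.  Errors if F0 approaches zero
    (division-unsafe), reporting where.
    """
    f465 = lowpass(sess.f465, sess.fs, lowpass_hz)
    f405 = lowpass(sess.f405, sess.fs, lowpass_hz)
    if fit_offset:
        A = np.column_stack([f405, np.ones_like(f405)])
    else:
        A = f405[:, None]
    coef, *_ = np.linalg.lstsq(A, f465, rcond=None)
    gain = float(coef[0])
    offset = float(coef[1]) if fit_offset else 0.0
    f0 = gain * f405 + offset

    scale = np.max(np.abs(f0))
    unsafe = np.abs(f0) <= 1e-6 * max(scale, 1e-300)
    if unsafe.any():
        i = int(np.flatnonzero(unsafe)[0])
        raise DegenerateDataError(
            f"fitted F0 crosses zero near t = {i / sess.fs:.2f} s; DF/F undefined"
        )
    dff_full = (f465 - f0) / f0
    dff = smooth_downsample(dff_full, sess.fs, out_fs, smooth_window_s)
    z = zscore_trace(dff) if zscore else None
    return CorrectedTrace(dff, out_fs, gain, offset, z)


@dataclass
class ETAResult:
    """Event-triggered average with percentile-bootstrap CI across onsets."""

    time_rel_s: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    snippets: np.ndarray  # (n_onsets_used, n_bins)
    n_used: int
    n_dropped: int


def event_triggered_average(
    trace: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    window: tuple[float, float] = (5.0, 10.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> ETAResult:
    """Align trace snippets to onsets and average with bootstrap CIs.

    ``window = (pre_s, post_s)`` spans [-pre, +post) around each onset.
    Onsets whose window leaves the trace are dropped with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    pre_s, post_s = window
    npre = int(round(pre_s * fs))
    npost = int(round(post_s * fs))
    snippets = []
    dropped = 0
    for on in np.asarray(onsets_s, dtype=float):
        i = int(round(on * fs))
        if i - npre < 0 or i + npost > trace.size:
            dropped += 1
            continue
        snippets.append(trace[i - npre : i + npost])
    if dropped:
        warnings.warn(f"dropped {dropped} onset(s) whose window leaves the session")
    if not snippets:
        raise InsufficientDataError("no onset window fits inside the session")
    snips = np.stack(snippets)
    lo, hi = bootstrap_ci(snips, n_boot=n_boot, seed=seed)
    time_rel = (np.arange(npre + npost) - npre) / fs
    return ETAResult(time_rel, snips.mean(axis=0), lo, hi, snips, len(snippets), dropped)
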