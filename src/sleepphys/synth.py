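"""Synthetic session generators with known ground truth.

Every downstream stage of the pipeline (scoring, calcium event analysis,
photometry correction, PSP quantification, stimulation statistics) is
exercised against sessions produced here, so each generator returns the
ground truth it drew: the hypnogram behind the EEG, the true event times
behind each fluorescence trace, the true transient behind the photometry
channels, and the exact kinetic parameters behind each PSP sweep.

Signals are built the way the real recordings look statistically, not
biophysically: EEG is a state-weighted mixture of band-limited Gaussian
noise (delta 0.5-4 Hz, theta 6-9 Hz, broadband 0.5-25 Hz), EMG is
band-limited noise with state-dependent amplitude, calcium traces are
Poisson event trains convolved with a single-exponential indicator kernel,
and photometry channels share a bleaching exponential and a low-frequency
motion artifact with a calcium transient present only in the signal
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import SimConfig
from .core import STATES, CellTraces, Hypnogram, PhotometrySession, Recording, Sweep
from .errors import ConfigError, ScheduleError

__all__ = [
    "CellGroundTruth",
    "PSPParams",
    "SweepSet",
    "TransientSpec",
    "gen_calcium",
    "gen_eeg_emg",
    "gen_hypnogram",
    "gen_photometry",
    "gen_psp_sweeps",
    "gen_schedule",
    "make_cell_profiles",
    "stationary_distribution",
]


# ---------------------------------------------------------------------------
# hypnogram

def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigen-decomposition)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_hypnogram(
    cfg: SimConfig,
    n_epochs: int,
    perturbation: pd.DataFrame | None = None,
    initial_state: str | None = None,
    wake_epochs: int | None = None,
) -> Hypnogram:
    """Simulate a Markov hypnogram over (W, N, R), optionally perturbed.

    ``perturbation`` is a schedule table (``onset_s``, ``offset_s``); during
    each on-phase the chain is forced to wake for ``wake_epochs`` epochs
    after the phase onset (default: epochs spanning the whole on-phase),
    emulating sleep deprivation by an intermittent sweeping rod that wakes
    the animal whenever it moves.

    The chain continues from the forced state, so perturbation produces the
    repeated wake-sleep transitions the deprivation paradigm is designed to
    induce.
    """
    if n_epochs < 1:
        raise ConfigError("n_epochs must be >= 1")
    P = cfg.transition_matrix
    rng = cfg.rng("hypnogram")
    pi = stationary_distribution(P)

    forced = np.zeros(n_epochs, dtype=bool)
    if perturbation is not None and len(perturbation):
        onsets_epoch = np.arange(n_epochs) * cfg.epoch_s
        for _, row in perturbation.iterrows():
            if wake_epochs is None:
                k = int(np.ceil((row["offset_s"] - row["onset_s"]) / cfg.epoch_s))
            else:
                k = int(wake_epochs)
            in_force = (onsets_epoch >= row["onset_s"]) & (
                onsets_epoch < row["onset_s"] + k * cfg.epoch_s
            )
            forced |= in_force

    if initial_state is None:
        state = int(rng.choice(3, p=pi))
    else:
        state = STATES.index(initial_state)

    out = np.empty(n_epochs, dtype=int)
    for i in range(n_epochs):
        if forced[i]:
            state = 0  # W
        out[i] = state
        state = int(rng.choice(3, p=P[state]))
    return Hypnogram(np.array(STATES)[out], epoch_s=cfg.epoch_s, provenance="simulated")


# ---------------------------------------------------------------------------
# EEG / EMG

def _unit_rms_band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float] | None
) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` and normalized to unit RMS."""
    x = rng.standard_normal(n)
    if band is not None:
        lo, hi = band
        nyq = fs / 2
        sos = signal.butter(4, [lo / nyq, min(hi, 0.95 * nyq) / nyq], "bandpass", output="sos")
        x = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _state_envelopes(
    hyp: Hypnogram, cfg: SimConfig, crossfade_s: float = 0.5
) -> np.ndarray:
    """Per-sample amplitude envelopes (4, n) for delta/theta/broadband/emg.

    Per-epoch gains (sqrt of the configured power weights) are expanded to
    sample rate and smoothed with a raised-cosine window of ``crossfade_s``
    so epoch boundaries cross-fade instead of stepping — scoring features
    must reflect state, not stitching artifacts.
    """
    fs = cfg.eeg_fs
    spe = int(round(hyp.epoch_s * fs))
    weights = np.array([cfg.state_band_power[s] for s in hyp.states])  # (E, 4)
    gains = np.sqrt(weights)
    env = np.repeat(gains, spe, axis=0).T  # (4, n)
    ntap = int(round(crossfade_s * fs))
    if ntap > 1:
        win = np.hanning(ntap)
        win = win / win.sum()
        env = np.stack(
            [signal.oaconvolve(e, win, mode="same") for e in env]
        )
    return env


def gen_eeg_emg(hyp: Hypnogram, cfg: SimConfig, n_eeg_channels: int = 2) -> Recording:
    """Synthesize an EEG/EMG recording consistent with a hypnogram.

    Each EEG channel mixes three independent unit-RMS noise streams (delta
    0.5-4 Hz, theta 6-9 Hz, broadband 0.5-25 Hz) with state-dependent
    amplitude envelopes; NREM epochs are delta-dominated, REM epochs
    theta-dominated, wake epochs broadband.  EMG is 10-100 Hz noise whose
    amplitude is high in wake and low in both sleep states.
    """
    if hyp.n_epochs == 0:
        raise ConfigError("hypnogram is empty")
    fs = cfg.eeg_fs
    n = int(round(hyp.n_epochs * hyp.epoch_s * fs))
    env = _state_envelopes(hyp, cfg)

    rng_eeg = cfg.rng("eeg")
    eeg_channels = []
    for _ in range(n_eeg_channels):
        d = _unit_rms_band_noise(rng_eeg, n, fs, (0.5, 4.0))
        t = _unit_rms_band_noise(rng_eeg, n, fs, (6.0, 9.0))
        b = _unit_rms_band_noise(rng_eeg, n, fs, (0.5, 25.0))
        eeg_channels.append(
            cfg.eeg_amp_uv * (d * env[0] + t * env[1] + b * env[2])
        )

    rng_emg = cfg.rng("emg")
    m = _unit_rms_band_noise(rng_emg, n, fs, (10.0, 100.0))
    emg = cfg.emg_amp_uv * m * env[3]
    return Recording(np.stack(eeg_channels), emg, fs)


# ---------------------------------------------------------------------------
# calcium

@dataclass
class CellGroundTruth:
    """True events behind one synthetic cell trace."""

    cell_id: str
    cell_class: str  # preferred state label, or "none"
    rates_per_min: dict[str, float]
    event_times_s: np.ndarray
    event_magnitudes: np.ndarray


def make_cell_profiles(
    n_cells: int,
    class_fractions: dict[str, float] | None = None,
    preferred_rate: float = 5.0,
    other_rate: float = 1.0,
) -> pd.DataFrame:
    """Cell population profile table (cell_id, cell_class, rate_W/N/R).

    Default class composition mirrors the recorded population: a majority
    of NREM-active cells with smaller REM-active and wake-active groups
    (57% / 16% / 27%).  Each cell fires at ``preferred_rate`` events/min in
    its preferred state and ``other_rate`` elsewhere (5:1 by default).
    """
    if class_fractions is None:
        class_fractions = {"N": 0.57, "R": 0.16, "W": 0.27}
    classes: list[str] = []
    # deterministic largest-remainder allocation of class counts
    items = sorted(class_fractions.items())
    counts = {s: int(np.floor(f * n_cells)) for s, f in items}
    rem = n_cells - sum(counts.values())
    by_frac = sorted(items, key=lambda kv: -(kv[1] * n_cells - np.floor(kv[1] * n_cells)))
    for s, _ in by_frac[:rem]:
        counts[s] += 1
    for s, _ in items:
        classes.extend([s] * counts[s])
    rows = []
    for i, cls in enumerate(classes):
        rates = {s: (preferred_rate if s == cls else other_rate) for s in STATES}
        rows.append(
            {
                "cell_id": f"cell_{i + 1:04d}",
                "cell_class": cls,
                "rate_W": rates["W"],
                "rate_N": rates["N"],
                "rate_R": rates["R"],
            }
        )
    return pd.DataFrame(rows)


def gen_calcium(
    hyp: Hypnogram,
    cell_profiles: pd.DataFrame,
    cfg: SimConfig,
    tau_s: float = 1.5,
    noise_sd: float = 0.05,
    baseline: float = 1.0,
    magnitude_sigma: float = 0.3,
) -> tuple[CellTraces, list[CellGroundTruth]]:
    """Simulate fluorescence traces as state-modulated Poisson event trains.

    Per cell, event times are drawn from an inhomogeneous Poisson process
    whose rate (events/min) depends on the current hypnogram state; each
    event carries a log-normal magnitude (median 1) and is convolved with a
    single-exponential decay kernel (``tau_s``, GCaMP6f-scale) sampled at
    ``cfg.ca_fs``.  Gaussian noise of SD ``noise_sd`` is added on top of a
    flat baseline.
    """
    for col in ("rate_W", "rate_N", "rate_R"):
        if np.any(cell_profiles[col].to_numpy() < 0):
            raise ConfigError("event rates must be nonnegative (events/min)")
    fs = cfg.ca_fs
    n_frames = int(round(hyp.duration_s * fs))
    gamma = float(np.exp(-1.0 / (tau_s * fs)))
    rng = cfg.rng("calcium")

    traces = np.empty((len(cell_profiles), n_frames))
    truths: list[CellGroundTruth] = []
    for ci, row in enumerate(cell_profiles.itertuples(index=False)):
        rates = {"W": row.rate_W, "N": row.rate_N, "R": row.rate_R}
        times: list[float] = []
        for e in range(hyp.n_epochs):
            lam = rates[hyp.states[e]] * hyp.epoch_s / 60.0
            k = rng.poisson(lam)
            if k:
                times.extend(e * hyp.epoch_s + rng.uniform(0, hyp.epoch_s, k))
        times_arr = np.sort(np.asarray(times))
        mags = (
            rng.lognormal(0.0, magnitude_sigma, times_arr.size)
            if magnitude_sigma > 0
            else np.ones(times_arr.size)
        )
        s = np.zeros(n_frames)
        if times_arr.size:
            idx = np.minimum((times_arr * fs).astype(int), n_frames - 1)
            np.add.at(s, idx, mags)
        clean = signal.lfilter([1.0], [1.0, -gamma], s)
        noise = rng.standard_normal(n_frames) * noise_sd if noise_sd > 0 else 0.0
        traces[ci] = baseline + clean + noise
        truths.append(
            CellGroundTruth(
                cell_id=row.cell_id,
                cell_class=getattr(row, "cell_class", "none"),
                rates_per_min=rates,
                event_times_s=times_arr,
                event_magnitudes=mags,
            )
        )
    return CellTraces(traces, fs, list(cell_profiles["cell_id"])), truths


# ---------------------------------------------------------------------------
# photometry

@dataclass
class TransientSpec:
    """True calcium transient added to the 465 nm channel only.

    ``onsets_s=None`` places one transient at the onset of every NREM bout
    of the hypnogram (the population recorded here is NREM-active).
    """

    onsets_s: np.ndarray | None = None
    amplitude: float = 0.2
    rise_s: float = 0.5
    decay_s: float = 3.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "rise_s", "decay_s"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"transient {name} must be finite")


def _double_exp_kernel(fs: float, rise_s: float, decay_s: float, dur_s: float) -> np.ndarray:
    t = np.arange(int(round(dur_s * fs))) / fs
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_photometry(
    hyp: Hypnogram,
    cfg: SimConfig,
    transient_spec: TransientSpec | None = None,
    bleach_tau_s: float = 1200.0,
    baseline_405: float = 1.0,
    gain_465: float = 2.0,
    offset_465: float = 0.5,
    artifact_sd: float = 0.02,
    noise_sd: float = 0.005,
) -> tuple[PhotometrySession, np.ndarray]:
    """Simulate a dual-channel photometry session; returns the true transient.

    The 405 nm isosbestic channel is baseline x exponential bleach plus a
    shared low-frequency (<1.5 Hz) motion artifact plus sensor noise; the
    465 nm channel is an affine transform (``gain_465``, ``offset_465``) of
    the same bleach-plus-artifact with the calcium transient and its own
    independent noise added.  The returned transient trace is in raw 465
    units on the ``cfg.photom_fs`` grid.
    """
    if transient_spec is None:
        transient_spec = TransientSpec()
    fs = cfg.photom_fs
    n = int(round(hyp.duration_s * fs))
    t = np.arange(n) / fs
    rng = cfg.rng("photometry")

    bleach = baseline_405 * np.exp(-t / bleach_tau_s)
    if artifact_sd > 0:
        raw = rng.standard_normal(n)
        nyq = fs / 2
        sos = signal.butter(4, 1.5 / nyq, "lowpass", output="sos")
        art = signal.sosfiltfilt(sos, raw)
        art = art / np.sqrt(np.mean(art**2)) * artifact_sd
    else:
        art = np.zeros(n)

    onsets = transient_spec.onsets_s
    if onsets is None:
        states = hyp.states
        starts = np.flatnonzero(
            (states == "N") & np.r_[True, states[:-1] != "N"][: states.size]
        )
        onsets = starts * hyp.epoch_s
    transient = np.zeros(n)
    if transient_spec.amplitude != 0 and len(onsets):
        kern = transient_spec.amplitude * _double_exp_kernel(
            fs, transient_spec.rise_s, transient_spec.decay_s, 8 * transient_spec.decay_s
        )
        for on in np.asarray(onsets, dtype=float):
            i = int(round(on * fs))
            if 0 <= i < n:
                j = min(n, i + kern.size)
                transient[i:j] += kern[: j - i]

    shared = bleach + art
    n405 = rng.standard_normal(n) * noise_sd if noise_sd > 0 else 0.0
    n465 = rng.standard_normal(n) * noise_sd if noise_sd > 0 else 0.0
    f405 = shared + n405
    f465 = gain_465 * shared + offset_465 + transient + n465
    return PhotometrySession(f465, f405, fs), transient


# ---------------------------------------------------------------------------
# PSP sweeps

@dataclass
class PSPParams:
    """Ground-truth kinetics of a synthetic postsynaptic response."""

    amplitude: float = 5.0  # mV (or pA for currents; sign via polarity)
    latency_ms: float = 2.0
    rise_ms: float = 0.5
    decay_ms: float = 10.0
    noise_sd: float = 0.1
    baseline: float = -65.0

    def __post_init__(self) -> None:
        if self.latency_ms < 0:
            raise ConfigError("latency must be nonnegative")
        if self.rise_ms >= self.decay_ms:
            raise ConfigError(
                "rise time constant must be smaller than decay (kernel would be non-positive)"
            )
        if self.rise_ms <= 0:
            raise ConfigError("rise time constant must be positive")


@dataclass
class SweepSet:
    """A set of equally sized sweeps sharing a stimulation onset."""

    sweeps: np.ndarray  # (n_sweeps, n_samples)
    fs: float
    stim_onset_s: float
    params: PSPParams
    polarity: str = "depolarizing"

    def sweep(self, i: int) -> Sweep:
        return Sweep(self.sweeps[i], self.fs, self.stim_onset_s, self.polarity)

    def __len__(self) -> int:
        return int(self.sweeps.shape[0])


def psp_kernel(fs: float, rise_ms: float, decay_ms: float, dur_s: float) -> np.ndarray:
    """Difference-of-exponentials PSP kernel normalized to unit peak."""
    t = np.arange(int(round(dur_s * fs))) / fs * 1000.0  # ms
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    # analytic peak of exp(-t/d) - exp(-t/r) at t* = ln(d/r) * r*d/(d-r)
    tstar = np.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)
    peak = np.exp(-tstar / decay_ms) - np.exp(-tstar / rise_ms)
    return k / peak


def gen_psp_sweeps(
    psp_params: PSPParams,
    n_sweeps: int,
    cfg: SimConfig,
    sweep_dur_s: float = 0.1,
    stim_onset_s: float = 0.02,
    polarity: str = "depolarizing",
) -> SweepSet:
    """Simulate evoked-response sweeps with known amplitude/latency/kinetics.

    Each sweep is a flat baseline plus a unit-peak difference-of-exponentials
    kernel starting at ``stim_onset + latency``, scaled to the requested
    amplitude (sign from ``polarity``), plus Gaussian noise.
    """
    if n_sweeps < 1:
        raise ConfigError("n_sweeps must be >= 1")
    fs = cfg.psp_fs
    n = int(round(sweep_dur_s * fs))
    i_start = int(round((stim_onset_s + psp_params.latency_ms / 1000.0) * fs))
    if i_start >= n:
        raise ConfigError("PSP onset falls outside the sweep")
    sign = -1.0 if polarity == "inward-current" else 1.0
    kern = psp_kernel(fs, psp_params.rise_ms, psp_params.decay_ms, sweep_dur_s)
    clean = np.full(n, psp_params.baseline)
    seg = min(kern.size, n - i_start)
    clean[i_start : i_start + seg] += sign * psp_params.amplitude * kern[:seg]

    rng = cfg.rng("psp")
    sweeps = np.tile(clean, (n_sweeps, 1))
    if psp_params.noise_sd > 0:
        sweeps = sweeps + rng.standard_normal(sweeps.shape) * psp_params.noise_sd
    return SweepSet(sweeps, fs, stim_onset_s, psp_params, polarity)


# ---------------------------------------------------------------------------
# schedules

def gen_schedule(kind: str, **params) -> pd.DataFrame:
    """Build a stimulation/perturbation schedule table (onset_s, offset_s, kind).

    ``intermittent_sweep``: repeating on/off cycles (defaults 30 s on, 90 s
    off) across ``span_s`` — the sleep-deprivation rod pattern.
    ``fixed_interval``: stimulation of ``on_s`` duration every ``interval_s``
    (default 45 min) starting at 0.
    """
    if kind == "intermittent_sweep":
        on_s = params.get("on_s", 30.0)
        off_s = params.get("off_s", 90.0)
        span_s = params["span_s"]
        include_partial = params.get("include_partial", True)
        if on_s <= 0 or off_s <= 0 or span_s < 0:
            raise ScheduleError("durations must be positive")
        cycle = on_s + off_s
        onsets = np.arange(0.0, span_s, cycle)
        offsets = np.minimum(onsets + on_s, span_s)
    elif kind == "fixed_interval":
        interval_s = params.get("interval_s", 2700.0)
        on_s = params.get("on_s", 120.0)
        span_s = params["span_s"]
        if interval_s <= 0 or on_s <= 0 or span_s < 0:
            raise ScheduleError("durations must be positive")
        include_partial = params.get("include_partial", True)
        onsets = np.arange(0.0, span_s, interval_s)
        offsets = np.minimum(onsets + on_s, span_s)
    else:
        raise ConfigError(f"unknown schedule kind {kind!r}")

    keep = offsets > onsets if include_partial else (offsets - onsets) >= on_s - 1e-12
    df = pd.DataFrame(
        {"onset_s": onsets[keep], "offset_s": offsets[keep], "kind": kind}
    )
    if np.any(df["offset_s"].to_numpy() <= df["onset_s"].to_numpy()):
        raise ScheduleError("schedule contains offset <= onset")
    return df
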