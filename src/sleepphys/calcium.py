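"""Per-cell calcium activity by vigilance state.

DF/F normalization against the whole-session mean, non-negative AR(1)
deconvolution into discrete events, per-state event AUC normalized to
state duration (activity per minute), the bounded two-state selectivity
index (a - b)/(a + b), cell classification into NREM-/REM-/wake-active
groups, and event AUC around wake<->NREM transitions in paired 30-s
windows.

The deconvolver is a pool-adjacent-violators non-negative AR(1) inversion
with fixed decay ``gamma = exp(-dt/tau)``: the isotonic projection of the
trace onto the cone of AR(1) responses to nonnegative inputs.  It is the
sparsity-free core of fast online deconvolution methods, chosen here for
its analytic testability (a noiseless kernel inverts exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import STATES, EventTrain, Hypnogram
from .errors import AlignmentError, ConfigError, DegenerateDataError
from .score import segment_bouts


def compute_dff(trace: np.ndarray) -> np.ndarray:
    """DF/F against the session mean: (F - mean(F)) / mean(F).

    The output has zero mean by construction and is invariant to rescaling
    the raw trace.
    """
    trace = np.asarray(trace, dtype=float)
    m = trace.mean()
    if m == 0:
        raise DegenerateDataError("session-mean fluorescence is zero; DF/F undefined")
    return (trace - m) / m


def _oasis_ar1(y: np.ndarray, gamma: float) -> np.ndarray:
    """Non-negative AR(1) deconvolution by pool adjacent violators.

    Finds the denoised trace c minimizing ||c - y||^2 subject to
    s_t = c_t - gamma * c_{t-1} >= 0, and returns s.  Pools are tuples
    (value, weight, start, length); a pool is merged into its predecessor
    whenever the non-negativity constraint between them is violated.
    """
    n = y.size
    # pools: v (weighted value), w (weight), t (start), l (length)
    v = np.empty(n)
    w = np.empty(n)
    t = np.empty(n, dtype=int)
    length = np.empty(n, dtype=int)
    k = -1
    for i in range(n):
        k += 1
        v[k], w[k], t[k], length[k] = y[i], 1.0, i, 1
        while k > 0 and v[k] / w[k] < gamma ** length[k - 1] * (v[k - 1] / w[k - 1]):
            g = gamma ** length[k - 1]
            v[k - 1] += g * v[k]
            w[k - 1] += g * g * w[k]
            length[k - 1] += length[k]
            k -= 1
    c = np.empty(n)
    for j in range(k + 1):
        base = max(v[j] / w[j], 0.0)
        idx = np.arange(length[j])
        c[t[j] : t[j] + length[j]] = base * gamma**idx
    s = np.empty(n)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return np.maximum(s, 0.0)


def estimate_noise_sd(dff: np.ndarray, gamma: float) -> float:
    """Robust noise SD from the AR(1) innovation residual (MAD-based)."""
    resid = dff[1:] - gamma * dff[:-1]
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(mad / 0.6744897501960817 / np.sqrt(1.0 + gamma**2))


def detect_events(
    dff: np.ndarray,
    decay_tau_s: float,
    fs: float,
    min_magnitude: float | None = None,
    cell_id: str = "",
    exclude_windows: list[tuple[float, float]] | None = None,
) -> EventTrain:
    """Deconvolve a DF/F trace into discrete events.

    The trace is inverted with the fixed-gamma non-negative AR(1)
    deconvolver; contiguous supra-threshold runs of the deconvolved
    activity are merged into single events carrying the summed magnitude,
    timestamped at the run onset.  ``min_magnitude=None`` uses 3x the
    MAD-estimated noise SD.  ``exclude_windows`` drops events inside the
    given (onset, offset) intervals — the programmatic replacement for
    manual review of motion artifacts.
    """
    if decay_tau_s <= 0:
        raise ConfigError("decay_tau_s must be positive")
    dff = np.asarray(dff, dtype=float)
    gamma = float(np.exp(-1.0 / (decay_tau_s * fs)))
    s = _oasis_ar1(dff, gamma)
    if min_magnitude is None:
        min_magnitude = 3.0 * estimate_noise_sd(dff, gamma)

    above = s > min_magnitude
    if not above.any():
        return EventTrain(np.empty(0), np.empty(0), cell_id)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    times = starts / fs
    mags = np.array([s[a:b].sum() for a, b in zip(starts, ends)])

    if exclude_windows:
        keep = np.ones(times.size, dtype=bool)
        for lo, hi in exclude_windows:
            keep &= ~((times >= lo) & (times < hi))
        times, mags = times[keep], mags[keep]
    return EventTrain(times, mags, cell_id)


def reconvolve(events: EventTrain, n_frames: int, decay_tau_s: float, fs: float) -> np.ndarray:
    """Reconstruct the noiseless trace implied by an event train (AR(1) kernel)."""
    gamma = float(np.exp(-1.0 / (decay_tau_s * fs)))
    s = np.zeros(n_frames)
    idx = np.minimum((events.times_s * fs).round().astype(int), n_frames - 1)
    np.add.at(s, idx, events.magnitudes)
    return signal.lfilter([1.0], [1.0, -gamma], s)


@dataclass
class StateActivity:
    """Per-state event AUC normalized to minutes spent in each state."""

    auc_per_min: dict[str, float]
    state_minutes: dict[str, float]
    undefined_states: set[str] = field(default_factory=set)
    cell_id: str = ""


def state_auc(events: EventTrain, hyp: Hypnogram) -> StateActivity:
    """Event AUC per minute of each state.

    Each event is assigned to the epoch containing its onset time
    (half-open epochs); per state, summed magnitudes are divided by the
    minutes spent in that state.  States of zero duration are flagged
    undefined rather than reported as zero activity.
    """
    if events.n_events and (
        events.times_s[0] < 0 or events.times_s[-1] >= hyp.duration_s
    ):
        raise AlignmentError("event times fall outside the hypnogram span")
    minutes = {s: sec / 60.0 for s, sec in hyp.state_seconds().items()}
    sums = dict.fromkeys(STATES, 0.0)
    if events.n_events:
        ev_states = hyp.state_at(events.times_s)
        for s in STATES:
            sums[s] = float(events.magnitudes[ev_states == s].sum())
    auc = {}
    undefined = set()
    for s in STATES:
        if minutes[s] > 0:
            auc[s] = sums[s] / minutes[s]
        else:
            auc[s] = np.nan
            undefined.add(s)
    return StateActivity(auc, minutes, undefined, events.cell_id)


def selectivity_index(auc_a: float, auc_b: float) -> float:
    """Bounded selectivity between two states: (a - b) / (a + b).

    Ranges over [-1, 1]; 0 means no selectivity.  Undefined (NaN, not 0)
    when both activities are zero.
    """
    if auc_a < 0 or auc_b < 0:
        raise ConfigError("AUC activities must be nonnegative")
    denom = auc_a + auc_b
    if denom == 0:
        return float("nan")
    return (auc_a - auc_b) / denom


@dataclass
class SelectivityResult:
    """Cell-level selectivity indices and class label."""

    cell_id: str
    nw_index: float  # NREM vs wake
    rw_index: float  # REM vs wake
    cell_class: str  # NREM-active | REM-active | wake-active | unclassified
    flags: set[str] = field(default_factory=set)


CLASS_BY_STATE = {"N": "NREM-active", "R": "REM-active", "W": "wake-active"}


def classify_cells(
    activities: list[StateActivity],
    margin: float = 0.2,
    min_state_minutes: float = 1.0,
) -> list[SelectivityResult]:
    """Classify cells by where their activity concentrates.

    NREM-active: NREM AUC is the strict maximum and the N-W index exceeds
    the margin; REM-active analogously on the R-W index; wake-active when
    both indices are at or below minus the margin; otherwise unclassified.
    Cells whose session covers any state for less than
    ``min_state_minutes`` are flagged unclassifiable.
    """
    out = []
    for act in activities:
        flags: set[str] = set()
        if any(
            act.state_minutes[s] < min_state_minutes or s in act.undefined_states
            for s in STATES
        ):
            out.append(
                SelectivityResult(act.cell_id, np.nan, np.nan, "unclassified", {"missing-state"})
            )
            continue
        a = act.auc_per_min
        nw = selectivity_index(a["N"], a["W"])
        rw = selectivity_index(a["R"], a["W"])
        if np.isnan(nw) or np.isnan(rw):
            flags.add("undefined-index")
        cls = "unclassified"
        if not flags:
            if a["N"] > a["W"] and a["N"] > a["R"] and nw >= margin:
                cls = "NREM-active"
            elif a["R"] > a["W"] and a["R"] > a["N"] and rw >= margin:
                cls = "REM-active"
            elif nw <= -margin and rw <= -margin:
                cls = "wake-active"
        out.append(SelectivityResult(act.cell_id, nw, rw, cls, flags))
    return out


def selectivity_frame(results: list[SelectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "nw_index": [r.nw_index for r in results],
            "rw_index": [r.rw_index for r in results],
            "cell_class": [r.cell_class for r in results],
        }
    )


def transition_activity(
    events: EventTrain,
    hyp: Hypnogram,
    window_s: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event AUC in paired windows around wake<->NREM transitions.

    For every W->N and N->W bout boundary whose flanking bouts both last at
    least ``window_s``, activity is summed over the ``window_s`` before and
    after the boundary and normalized per minute.  Transitions with a
    shorter episode on either side are excluded.  Returns the per-transition
    table and a paired-t summary per transition type.
    """
    bouts = segment_bouts(hyp)
    rows = []
    for i in range(len(bouts) - 1):
        pre, post = bouts.iloc[i], bouts.iloc[i + 1]
        pair = (pre["state"], post["state"])
        if pair not in (("W", "N"), ("N", "W")):
            continue
        if pre["duration_s"] < window_s or post["duration_s"] < window_s:
            continue
        b = post["onset_s"]
        in_pre = (events.times_s >= b - window_s) & (events.times_s < b)
        in_post = (events.times_s >= b) & (events.times_s < b + window_s)
        per_min = 60.0 / window_s
        rows.append(
            {
                "transition": f"{pre['state']}->{post['state']}",
                "boundary_s": b,
                "pre_auc_per_min": float(events.magnitudes[in_pre].sum()) * per_min,
                "post_auc_per_min": float(events.magnitudes[in_post].sum()) * per_min,
            }
        )
    table = pd.DataFrame(rows, columns=["transition", "boundary_s", "pre_auc_per_min", "post_auc_per_min"])

    summaries = []
    for name, grp in table.groupby("transition"):
        pre = grp["pre_auc_per_min"].to_numpy()
        post = grp["post_auc_per_min"].to_numpy()
        if len(grp) >= 2 and np.ptp(post - pre) > 0:
            t, p = stats.ttest_rel(post, pre)
        else:
            t, p = np.nan, np.nan
        summaries.append(
            {
                "transition": name,
                "n": len(grp),
                "mean_pre": pre.mean(),
                "mean_post": post.mean(),
                "t_stat": t,
                "p_value": p,
            }
        )
    summary = pd.DataFrame(
        summaries, columns=["transition", "n", "mean_pre", "mean_post", "t_stat", "p_value"]
    )
    return table, summary
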