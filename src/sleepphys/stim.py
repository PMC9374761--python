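"""Optogenetic stimulation trials: scheduling and outcome statistics.

Covers both triggering modes used in closed-loop sleep-induction
experiments — wake-triggered stimulation (trigger after 5 min of
continuous movement, minimum 30 min between trials) and fixed-interval
stimulation (every 45 min) — plus the trial statistics built on the scored
hypnogram: per-bin brain-state probability traces around laser onset with
percentile-bootstrap CIs, the wake-to-NREM transition probability with a
binomial CI, and the comparison of optogenetically induced vs natural
NREM bouts (durations and relative delta power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import STATES, Hypnogram
from .errors import ConfigError, InsufficientDataError, ScheduleError
from .score import Spectrogram, relative_delta, segment_bouts
from .statsutil import bootstrap_ci


def simulate_closed_loop(
    indicator: np.ndarray,
    dt_s: float,
    wake_persist_s: float = 300.0,
    min_interval_s: float = 1800.0,
) -> np.ndarray:
    """Wake-triggered stimulation onsets from a movement/wake indicator.

    Scanning forward, a trigger fires as soon as the indicator has been
    continuously active for ``wake_persist_s`` *and* at least
    ``min_interval_s`` has elapsed since the previous trigger.  The
    persistence counter resets on inactivity and on each trigger.  Onset
    times mark the end of the qualifying persistence period.
    """
    if dt_s <= 0:
        raise ConfigError("dt_s must be positive")
    active = np.asarray(indicator).astype(bool)
    onsets: list[float] = []
    persist = 0.0
    last = -np.inf
    for i, a in enumerate(active):
        if a:
            persist += dt_s
        else:
            persist = 0.0
        t_end = (i + 1) * dt_s
        if persist >= wake_persist_s and t_end - last >= min_interval_s:
            onsets.append(t_end)
            last = t_end
            persist = 0.0
    return np.asarray(onsets)


def fixed_interval_onsets(span_s: float, interval_s: float = 2700.0) -> np.ndarray:
    """Stimulation onsets at 0, interval, 2*interval, ... strictly inside span."""
    if interval_s <= 0:
        raise ScheduleError("interval_s must be positive")
    if span_s < 0:
        raise ScheduleError("span_s must be nonnegative")
    return np.arange(0.0, span_s, interval_s)


@dataclass
class StateProbabilityTrace:
    """Fraction of trials in each state per time bin relative to laser onset."""

    time_rel_s: np.ndarray  # bin onsets relative to stimulation onset
    p: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        data = {"time_rel_s": self.time_rel_s}
        for s in STATES:
            data[f"p_{s}"] = self.p[s]
            data[f"ci_low_{s}"] = self.ci_low[s]
            data[f"ci_high_{s}"] = self.ci_high[s]
        return pd.DataFrame(data)


def state_probability_trace(
    hyp: Hypnogram,
    onsets_s: np.ndarray,
    window: tuple[float, float] = (-240.0, 480.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> StateProbabilityTrace:
    """Brain-state probability around stimulation onsets with bootstrap CIs.

    Per relative epoch-length bin, the per-state probability is the
    fraction of trials whose hypnogram epoch at that latency carries the
    state; probabilities partition to 1 in every bin.  CIs are percentile
    bootstrap over trials.  Trials whose window leaves the session are
    dropped with a warning.
    """
    rel = np.arange(window[0], window[1], hyp.epoch_s)
    trials = []
    dropped = 0
    for on in np.asarray(onsets_s, dtype=float):
        t = on + rel
        if t[0] < 0 or t[-1] >= hyp.duration_s:
            dropped += 1
            continue
        trials.append(hyp.state_at(t))
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) whose window leaves the session")
    if not trials:
        raise InsufficientDataError("no usable stimulation trials")
    mat = np.stack(trials)  # (n_trials, n_bins) of labels
    p, lo, hi = {}, {}, {}
    for si, s in enumerate(STATES):
        onehot = (mat == s).astype(float)
        p[s] = onehot.mean(axis=0)
        lo[s], hi[s] = bootstrap_ci(onehot, n_boot=n_boot, seed=seed + si)
    return StateProbabilityTrace(rel, p, lo, hi, len(trials))


@dataclass
class TransitionProbabilityResult:
    """Wake-to-NREM transition probability across stimulation trials."""

    probability: float
    n_success: int
    n_trials: int
    n_excluded: int  # trials not starting from wake
    ci_low: float
    ci_high: float
    trials: pd.DataFrame
    by_frequency: pd.DataFrame | None = None


def make_stim_trials(
    hyp: Hypnogram,
    onsets_s: np.ndarray,
    duration_s: float = 120.0,
    frequency_hz: float | np.ndarray = 20.0,
) -> pd.DataFrame:
    """Trial table from onsets: onset, offset, frequency, pre-state at onset."""
    onsets = np.asarray(onsets_s, dtype=float)
    freq = np.broadcast_to(np.asarray(frequency_hz, dtype=float), onsets.shape)
    pre = [
        hyp.state_at(on).item() if 0 <= on < hyp.duration_s else "?" for on in onsets
    ]
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "offset_s": onsets + duration_s,
            "frequency_hz": freq,
            "pre_state": pre,
        }
    )


def transition_probability(
    trials: pd.DataFrame,
    hyp: Hypnogram,
    success_window_post_s: float = 300.0,
    min_nrem_s: float = 30.0,
) -> TransitionProbabilityResult:
    """Fraction of wake-onset trials followed by induced NREM sleep.

    A trial counts as a success when a NREM bout of at least ``min_nrem_s``
    begins inside [laser onset, laser offset + ``success_window_post_s``) —
    the window spans the stimulation itself and the minutes after offset,
    since transitions occur during stimulation for some targets and after
    offset for others.  Trials not starting from wake are excluded from the
    denominator but kept (marked) in the returned trial table.  The CI is
    exact binomial (Clopper-Pearson).  A per-frequency breakdown is
    included when the trial table carries a ``frequency_hz`` column.
    """
    bouts = segment_bouts(hyp)
    nrem = bouts[(bouts["state"] == "N") & (bouts["duration_s"] >= min_nrem_s)]
    nrem_onsets = nrem["onset_s"].to_numpy()

    table = trials.copy()
    outcomes = []
    latencies = []
    for row in table.itertuples(index=False):
        if row.pre_state != "W":
            outcomes.append("excluded")
            latencies.append(np.nan)
            continue
        w_lo, w_hi = row.onset_s, row.offset_s + success_window_post_s
        hits = nrem_onsets[(nrem_onsets >= w_lo) & (nrem_onsets < w_hi)]
        if hits.size:
            outcomes.append("transition")
            latencies.append(float(hits[0] - row.onset_s))
        else:
            outcomes.append("no-transition")
            latencies.append(np.nan)
    table["outcome"] = outcomes
    table["latency_to_nrem_s"] = latencies

    wake = table[table["outcome"] != "excluded"]
    n = len(wake)
    if n == 0:
        raise InsufficientDataError("no stimulation trials start from wake")
    k = int((wake["outcome"] == "transition").sum())
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")

    by_freq = None
    if "frequency_hz" in wake.columns and wake["frequency_hz"].nunique() > 1:
        by_freq = (
            wake.assign(success=(wake["outcome"] == "transition").astype(float))
            .groupby("frequency_hz", as_index=False)
            .agg(n_trials=("success", "size"), probability=("success", "mean"))
        )
    return TransitionProbabilityResult(
        probability=k / n,
        n_success=k,
        n_trials=n,
        n_excluded=int((table["outcome"] == "excluded").sum()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        trials=table,
        by_frequency=by_freq,
    )


@dataclass
class InducedVsNatural:
    """Induced and natural NREM bout samples with unpaired comparisons."""

    induced: pd.DataFrame
    natural: pd.DataFrame
    duration_test: dict | None
    delta_test: dict | None


def _bout_rel_delta(bout, rd: np.ndarray, epoch_s: float) -> float:
    i0 = int(np.ceil(bout.onset_s / epoch_s))
    i1 = int(np.floor(bout.offset_s / epoch_s))
    i1 = min(i1, rd.size)
    if i1 <= i0:
        return float("nan")
    return float(rd[i0:i1].mean())


def induced_vs_natural(
    hyp: Hypnogram,
    spec: Spectrogram,
    onsets_s: np.ndarray,
    post_s: float = 600.0,
    natural_margin_s: float = 900.0,
) -> InducedVsNatural:
    """Compare optogenetically induced with natural NREM bouts.

    Induced sample: the first NREM bout (if any) beginning within
    ``post_s`` (10 min) after each laser onset.  Natural sample: every NREM
    bout whose onset is at least ``natural_margin_s`` (15 min) from every
    laser onset in the same session.  For both, bout duration and the
    bout-mean relative delta power are collected and compared with
    two-sided unpaired t-tests (no test when either sample has < 2 bouts).
    """
    bouts = segment_bouts(hyp)
    nrem = bouts[bouts["state"] == "N"].reset_index(drop=True)
    rd = relative_delta(spec)
    onsets = np.asarray(onsets_s, dtype=float)

    induced_rows = []
    used = set()
    for on in onsets:
        cand = nrem[(nrem["onset_s"] >= on) & (nrem["onset_s"] < on + post_s)]
        if len(cand):
            b = cand.iloc[0]
            key = float(b["onset_s"])
            if key not in used:
                used.add(key)
                induced_rows.append(
                    {
                        "stim_onset_s": on,
                        "onset_s": b["onset_s"],
                        "duration_s": b["duration_s"],
                        "rel_delta": _bout_rel_delta(b, rd, hyp.epoch_s),
                    }
                )
    induced = pd.DataFrame(
        induced_rows, columns=["stim_onset_s", "onset_s", "duration_s", "rel_delta"]
    )

    natural_rows = []
    for b in nrem.itertuples(index=False):
        if onsets.size and np.min(np.abs(b.onset_s - onsets)) < natural_margin_s:
            continue
        natural_rows.append(
            {
                "onset_s": b.onset_s,
                "duration_s": b.duration_s,
                "rel_delta": _bout_rel_delta(b, rd, hyp.epoch_s),
            }
        )
    natural = pd.DataFrame(natural_rows, columns=["onset_s", "duration_s", "rel_delta"])

    def _test(a: np.ndarray, b: np.ndarray) -> dict | None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            return None
        t, p = stats.ttest_ind(a, b)
        return {
            "mean_induced": float(a.mean()),
            "mean_natural": float(b.mean()),
            "t_stat": float(t),
            "p_value": float(p),
            "n_induced": int(a.size),
            "n_natural": int(b.size),
        }

    return InducedVsNatural(
        induced,
        natural,
        _test(induced["duration_s"].to_numpy(), natural["duration_s"].to_numpy()),
        _test(induced["rel_delta"].to_numpy(), natural["rel_delta"].to_numpy()),
    )
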