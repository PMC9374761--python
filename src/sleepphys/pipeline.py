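"""Declarative configuration and the end-to-end pipeline runner.

A pipeline run is fully described by a YAML document plus a seed: the
synthetic session is generated, scored, and pushed through the calcium,
photometry, PSP, and stimulation analyses, with every artifact written as
columnar text next to a fully-resolved copy of the configuration and a
structured run log.  Identical (config, seed) pairs give byte-identical
data artifacts; the run log additionally carries wall-clock timestamps and
is the one file excluded from bitwise-reproducibility comparisons.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import io as sio
from . import photometry as ph
from . import psp as pspmod
from . import stim as st
from . import synth
from .config import SimConfig
from .core import Sweep
from .errors import ConfigError, InsufficientDataError
from .score import (
    Thresholds,
    classify_epochs,
    compute_spectrogram,
    extract_features,
    relative_delta,
    segment_bouts,
)

ALL_STAGES = ("simulate", "score", "calcium", "photometry", "psp", "stim")

#: Allowed configuration keys (nested).  Unknown keys are rejected up front.
_SCHEMA: dict = {
    "session": {"duration_min", "seed", "epoch_s", "eeg_fs", "ca_fs", "photom_fs"},
    "stages": None,  # list of stage names
    "simulate": {
        "n_cells",
        "preferred_rate",
        "other_rate",
        "ca_noise_sd",
        "ca_tau_s",
        "schedule_kind",
        "schedule_interval_s",
        "schedule_on_s",
        "schedule_off_s",
        "write_raw",
    },
    "score": {"theta_delta_threshold", "emg_threshold", "min_bout_s"},
    "calcium": {"decay_tau_s", "margin", "min_magnitude"},
    "photometry": {"lowpass_hz", "out_fs", "zscore"},
    "psp": {"n_sweeps", "amplitude", "latency_ms", "rise_ms", "decay_ms", "noise_sd"},
    "stim": {
        "duration_s",
        "success_window_post_s",
        "min_nrem_s",
        "n_boot",
        "trigger",
        "wake_persist_s",
        "min_interval_s",
    },
}

DEFAULT_CONFIG: dict = {
    "session": {
        "duration_min": 30,
        "seed": 0,
        "epoch_s": 2.0,
        "eeg_fs": 1000.0,
        "ca_fs": 10.0,
        "photom_fs": 100.0,
    },
    "stages": list(ALL_STAGES),
    "simulate": {
        "n_cells": 10,
        "preferred_rate": 5.0,
        "other_rate": 1.0,
        "ca_noise_sd": 0.05,
        "ca_tau_s": 1.5,
        "schedule_kind": "fixed_interval",
        "schedule_interval_s": 600.0,
        "schedule_on_s": 120.0,
        "schedule_off_s": 90.0,
        "write_raw": True,
    },
    "score": {"theta_delta_threshold": 1.0, "emg_threshold": None, "min_bout_s": 0.0},
    "calcium": {"decay_tau_s": 1.5, "margin": 0.2, "min_magnitude": None},
    "photometry": {"lowpass_hz": 2.0, "out_fs": 5.0, "zscore": False},
    "psp": {
        "n_sweeps": 5,
        "amplitude": 5.0,
        "latency_ms": 2.0,
        "rise_ms": 0.5,
        "decay_ms": 10.0,
        "noise_sd": 0.1,
    },
    "stim": {
        "duration_s": 120.0,
        "success_window_post_s": 300.0,
        "min_nrem_s": 30.0,
        "n_boot": 1000,
        "trigger": "schedule",  # or "closed_loop" (wake-triggered)
        "wake_persist_s": 300.0,
        "min_interval_s": 1800.0,
    },
}


def validate_config(doc: dict) -> dict:
    """Merge a (possibly partial) config document onto the defaults.

    Unknown sections or keys raise :class:`ConfigError` before any stage
    runs.
    """
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for section, value in doc.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if section == "stages":
            bad = set(value) - set(ALL_STAGES)
            if bad:
                raise ConfigError(f"unknown stages {sorted(bad)}")
            merged["stages"] = list(value)
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(value) - _SCHEMA[section]
        if bad:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(bad)}")
        merged[section].update(value)
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML config file (``None`` gives the defaults)."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return validate_config(doc)


def demo_config() -> dict:
    """The bundled demonstration configuration."""
    with resources.files("sleepphys").joinpath("data/demo_config.yaml").open() as fh:
        return validate_config(yaml.safe_load(fh))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def add(self, stage: str, **info) -> None:
        rec = {
            "wall_time": datetime.datetime.now().isoformat(timespec="seconds"),
            "stage": stage,
            **info,
        }
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute the configured stages in dependency order into ``out_dir``.

    Returns the output directory.  All randomness flows from the single
    session seed (``seed`` argument overriding ``session.seed``); each
    stage logs its parameters and the digests of the files it wrote.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config["session"]["seed"] = int(seed)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    log_path = out / "run_log.jsonl"
    if log_path.exists():
        log_path.unlink()
    log = _RunLog(log_path)

    ses = config["session"]
    cfg = SimConfig(
        seed=int(ses["seed"]),
        epoch_s=float(ses["epoch_s"]),
        eeg_fs=float(ses["eeg_fs"]),
        ca_fs=float(ses["ca_fs"]),
        photom_fs=float(ses["photom_fs"]),
    )
    n_epochs = int(round(ses["duration_min"] * 60 / cfg.epoch_s))
    stages = config["stages"]
    state: dict = {}
    summary: dict = {"seed": cfg.seed, "duration_min": ses["duration_min"]}

    if "simulate" in stages:
        sim = config["simulate"]
        if sim["schedule_kind"] == "fixed_interval":
            schedule = synth.gen_schedule(
                "fixed_interval",
                span_s=n_epochs * cfg.epoch_s,
                interval_s=sim["schedule_interval_s"],
                on_s=sim["schedule_on_s"],
            )
        else:
            schedule = synth.gen_schedule(
                "intermittent_sweep",
                span_s=n_epochs * cfg.epoch_s,
                on_s=sim["schedule_on_s"],
                off_s=sim["schedule_off_s"],
            )
        hyp = synth.gen_hypnogram(cfg, n_epochs)
        rec = synth.gen_eeg_emg(hyp, cfg)
        profiles = synth.make_cell_profiles(
            sim["n_cells"], preferred_rate=sim["preferred_rate"], other_rate=sim["other_rate"]
        )
        traces, truths = synth.gen_calcium(
            hyp, profiles, cfg, tau_s=sim["ca_tau_s"], noise_sd=sim["ca_noise_sd"]
        )
        phot, transient = synth.gen_photometry(hyp, cfg)
        psp_params = synth.PSPParams(
            amplitude=config["psp"]["amplitude"],
            latency_ms=config["psp"]["latency_ms"],
            rise_ms=config["psp"]["rise_ms"],
            decay_ms=config["psp"]["decay_ms"],
            noise_sd=config["psp"]["noise_sd"],
        )
        sweeps = synth.gen_psp_sweeps(psp_params, config["psp"]["n_sweeps"], cfg)

        sio.write_hypnogram(hyp, out / "hypnogram_true.tsv")
        sio.write_schedule(schedule, out / "schedule.tsv")
        sio.write_traces(traces, out / "calcium_traces.csv")
        pd.DataFrame(
            {
                "cell_id": [t.cell_id for t in truths],
                "cell_class": [t.cell_class for t in truths],
                "n_events": [t.event_times_s.size for t in truths],
            }
        ).to_csv(out / "truth_cells.csv", index=False)
        if sim["write_raw"]:
            sio.write_recording(rec, out / "recording.csv")
        written = ["hypnogram_true.tsv", "schedule.tsv", "calcium_traces.csv", "truth_cells.csv"]
        log.add(
            "simulate",
            seed=cfg.seed,
            n_epochs=n_epochs,
            outputs={f: _digest(out / f) for f in written},
        )
        state.update(
            hyp_true=hyp,
            rec=rec,
            traces=traces,
            truths=truths,
            phot=phot,
            transient=transient,
            sweeps=sweeps,
            schedule=schedule,
        )

    if "score" in stages:
        sc = config["score"]
        rec = state["rec"]
        spec = compute_spectrogram(rec)
        feats = extract_features(spec, rec)
        thr = None
        if sc["emg_threshold"] is not None:
            thr = Thresholds(emg_rms=sc["emg_threshold"], theta_delta=sc["theta_delta_threshold"])
        hyp = classify_epochs(feats, thresholds=thr)
        bouts = segment_bouts(hyp, min_bout_s=sc["min_bout_s"])
        feats = feats.assign(rel_delta=relative_delta(spec))
        feats.to_csv(out / "features.tsv", sep="\t", index=False, float_format=sio.FLOAT_FMT)
        sio.write_hypnogram(hyp, out / "hypnogram.tsv")
        bouts.to_csv(out / "bouts.tsv", sep="\t", index=False, float_format=sio.FLOAT_FMT)
        if "hyp_true" in state:
            truth = state["hyp_true"].states[: hyp.n_epochs]
            acc = float(np.mean(truth == hyp.states))
            summary["scoring_accuracy"] = acc
        log.add(
            "score",
            outputs={f: _digest(out / f) for f in ("features.tsv", "hypnogram.tsv", "bouts.tsv")},
            accuracy=summary.get("scoring_accuracy"),
        )
        state.update(spec=spec, feats=feats, hyp=hyp, bouts=bouts)

    hyp_for_analysis = state.get("hyp") or state.get("hyp_true")

    if "calcium" in stages:
        cc = config["calcium"]
        traces = state["traces"]
        trains = []
        for cid, tr in zip(traces.cell_ids, traces.traces):
            dff = ca.compute_dff(tr)
            trains.append(
                ca.detect_events(
                    dff, cc["decay_tau_s"], traces.fs, cc["min_magnitude"], cell_id=cid
                )
            )
        # scored hypnograms end two epochs early (trailing partial FFT
        # windows are dropped); clip late events so state AUC stays aligned
        from .core import EventTrain as _ET

        dur = hyp_for_analysis.duration_s
        clipped = [
            _ET(t.times_s[t.times_s < dur], t.magnitudes[t.times_s < dur], t.cell_id)
            for t in trains
        ]
        acts = [ca.state_auc(t, hyp_for_analysis) for t in clipped]
        results = ca.classify_cells(acts, margin=cc["margin"])
        sio.write_events(trains, out / "events.csv")
        pd.DataFrame(
            [
                {"cell_id": a.cell_id, **{f"auc_{s}": a.auc_per_min[s] for s in "WNR"}}
                for a in acts
            ]
        ).to_csv(out / "state_activity.csv", index=False, float_format=sio.FLOAT_FMT)
        ca.selectivity_frame(results).to_csv(
            out / "selectivity.csv", index=False, float_format=sio.FLOAT_FMT
        )
        if "truths" in state:
            truth_cls = {
                t.cell_id: ca.CLASS_BY_STATE.get(t.cell_class, "unclassified")
                for t in state["truths"]
            }
            hits = [r.cell_class == truth_cls[r.cell_id] for r in results]
            summary["cell_class_accuracy"] = float(np.mean(hits))
        log.add(
            "calcium",
            outputs={
                f: _digest(out / f)
                for f in ("events.csv", "state_activity.csv", "selectivity.csv")
            },
        )
        state.update(trains=trains)

    if "photometry" in stages:
        pc = config["photometry"]
        corrected = ph.correct_isosbestic(
            state["phot"],
            lowpass_hz=pc["lowpass_hz"],
            out_fs=pc["out_fs"],
            zscore=pc["zscore"],
        )
        t_out = np.arange(corrected.dff.size) / corrected.fs_out
        pd.DataFrame({"time_s": t_out, "dff": corrected.dff}).to_csv(
            out / "photometry_dff.csv", index=False, float_format=sio.FLOAT_FMT
        )
        if "transient" in state:
            truth5 = ph.smooth_downsample(
                state["transient"], state["phot"].fs, pc["out_fs"]
            )
            n = min(truth5.size, corrected.dff.size)
            if np.std(truth5[:n]) > 0:
                summary["photometry_transient_corr"] = float(
                    np.corrcoef(truth5[:n], corrected.dff[:n])[0, 1]
                )
        summary["photometry_fit_gain"] = corrected.fit_gain
        summary["photometry_fit_offset"] = corrected.fit_offset
        log.add("photometry", outputs={"photometry_dff.csv": _digest(out / "photometry_dff.csv")})

    if "psp" in stages:
        sweeps = state["sweeps"]
        avg = pspmod.average_sweeps([sweeps.sweep(i) for i in range(len(sweeps))])
        q = pspmod.quantify_sweep(avg)
        per_sweep = [pspmod.quantify_sweep(sweeps.sweep(i)) for i in range(len(sweeps))]
        rows = [
            {
                "sweep_id": "average",
                "detected": q.detected,
                "amplitude": q.amplitude,
                "rise_time_ms": q.rise_time_ms,
                "onset_latency_ms": q.onset_latency_ms,
            }
        ] + [
            {
                "sweep_id": f"sweep_{i + 1:02d}",
                "detected": s.detected,
                "amplitude": s.amplitude,
                "rise_time_ms": s.rise_time_ms,
                "onset_latency_ms": s.onset_latency_ms,
            }
            for i, s in enumerate(per_sweep)
        ]
        pd.DataFrame(rows).to_csv(out / "psp_quants.csv", index=False, float_format=sio.FLOAT_FMT)
        summary["psp_amplitude"] = q.amplitude
        summary["psp_latency_ms"] = q.onset_latency_ms
        log.add("psp", outputs={"psp_quants.csv": _digest(out / "psp_quants.csv")})

    if "stim" in stages:
        stc = config["stim"]
        if stc["trigger"] == "closed_loop":
            onsets = st.simulate_closed_loop(
                hyp_for_analysis.states == "W",
                hyp_for_analysis.epoch_s,
                wake_persist_s=stc["wake_persist_s"],
                min_interval_s=stc["min_interval_s"],
            )
        else:
            onsets = state["schedule"]["onset_s"].to_numpy()
        trials = st.make_stim_trials(hyp_for_analysis, onsets, duration_s=stc["duration_s"])
        trials.to_csv(out / "stim_trials.csv", index=False, float_format=sio.FLOAT_FMT)
        try:
            prob = st.transition_probability(
                trials,
                hyp_for_analysis,
                success_window_post_s=stc["success_window_post_s"],
                min_nrem_s=stc["min_nrem_s"],
            )
            summary["transition_probability"] = prob.probability
            prob.trials.to_csv(
                out / "stim_trials.csv", index=False, float_format=sio.FLOAT_FMT
            )
        except InsufficientDataError:
            summary["transition_probability"] = None
        try:
            trace = st.state_probability_trace(
                hyp_for_analysis, onsets, n_boot=stc["n_boot"], seed=cfg.seed
            )
            trace.to_frame().to_csv(
                out / "state_probability.csv", index=False, float_format=sio.FLOAT_FMT
            )
        except InsufficientDataError:
            pass
        log.add("stim", outputs={"stim_trials.csv": _digest(out / "stim_trials.csv")})

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.add("done", summary=summary)
    return out
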