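#!/usr/bin/env python
"""Isosbestic correction of a synthetic photometry session.

Simulates a 30-min dual-channel session with exponential bleaching, a
shared motion artifact, and NREM-onset calcium transients; runs the
2 Hz low-pass -> least-squares 405 fit -> DF/F -> smooth/downsample chain;
and measures how well the corrected trace recovers the true transient.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sleepphys import photometry as ph
from sleepphys import synth
from sleepphys.config import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    hyp = synth.gen_hypnogram(cfg, 900)
    sess, transient = synth.gen_photometry(hyp, cfg)
    corr = ph.correct_isosbestic(sess)

    truth = ph.smooth_downsample(transient, sess.fs, corr.fs_out)
    n = min(truth.size, corr.dff.size)
    r = float(np.corrcoef(truth[:n], corr.dff[:n])[0, 1])
    raw_r = float(np.corrcoef(transient, sess.f465)[0, 1])

    pd.DataFrame(
        [
            {
                "fit_gain": corr.fit_gain,
                "fit_offset": corr.fit_offset,
                "corr_dff_vs_truth": r,
                "corr_raw465_vs_truth": raw_r,
                "n_samples_5hz": n,
            }
        ]
    ).to_csv(args.out / "04_photometry.csv", index=False, float_format="%.6g")

    print(f"Least-squares 405 fit: gain {corr.fit_gain:.3f}, offset {corr.fit_offset:.3f}")
    print(f"Corrected dF/F vs true transient: r = {r:.3f}")
    print(f"(raw 465 channel vs truth: r = {raw_r:.3f} — bleaching and the shared")
    print(" artifact dominate before correction)")


if __name__ == "__main__":
    main()
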