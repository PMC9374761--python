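"""Seeded percentile-bootstrap helpers shared across modules."""

from __future__ import annotations

import numpy as np


def bootstrap_ci(
    data: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Percentile bootstrap CI for the mean over units (axis 0).

    ``data`` is (n_units,) or (n_units, n_bins); units (trials, animals,
    snippets) are resampled with replacement ``n_boot`` times and the
    (alpha/2, 1 - alpha/2) percentiles of the resampled means returned —
    scalars for 1-D input, per-bin arrays for 2-D input.
    """
    arr = np.asarray(data, dtype=float)
    scalar = arr.ndim == 1
    if scalar:
        arr = arr[:, None]
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = arr[idx].mean(axis=1)  # (n_boot, n_bins)
    lo = np.percentile(boot_means, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    if scalar:
        return float(lo[0]), float(hi[0])
    return lo, hi
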