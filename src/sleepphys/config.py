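"""Simulation configuration.

:class:`SimConfig` carries every rate and constant the synthetic-session
generators need, with defaults matching the recording conditions the
pipeline is designed for: 2-s scoring epochs, ~1 kHz EEG/EMG, 10 frames/s
single-photon calcium imaging, 100 Hz demodulated photometry, 10 kHz
patch-clamp sweeps.

Randomness discipline: one seed per session; each generator draws from its
own named substream (``cfg.rng("eeg")`` etc.) so adding a generator call
does not shift the draws of any other stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import STATES
from .errors import ConfigError

# Fixed substream identifiers: never reorder, only append.
_STREAMS = {
    "hypnogram": 0,
    "eeg": 1,
    "emg": 2,
    "calcium": 3,
    "photometry": 4,
    "psp": 5,
    "misc": 6,
}


def default_transition_matrix() -> np.ndarray:
    """Per-2-s-epoch Markov transition matrix over (W, N, R).

    Chosen for rodent light-phase statistics: mean wake and NREM bouts of
    ~2 min, mean REM bouts of ~1 min, no direct wake-to-REM transitions,
    REM always exiting to wake.  Stationary distribution ~ (0.455, 0.455,
    0.091), i.e. roughly half the session asleep with ~9% REM.
    """
    return np.array(
        [
            [59 / 60, 1 / 60, 0.0],
            [1 / 100, 1 - 1 / 100 - 1 / 150, 1 / 150],
            [1 / 30, 0.0, 29 / 30],
        ]
    )


def default_state_band_power() -> dict[str, tuple[float, float, float, float]]:
    """Relative power weights (delta, theta, broadband, emg) per state.

    Wake: desynchronized broadband EEG with high muscle tone; NREM:
    delta-dominated EEG with low tone; REM: theta-dominated EEG with atonia.
    The EMG wake/sleep power ratio is a free parameter of the generator
    (see the methods note); the default gives a ~6x RMS contrast.
    """
    return {
        "W": (1.0, 1.0, 2.0, 4.0),
        "N": (4.0, 1.0, 1.0, 0.1),
        "R": (1.0, 4.0, 0.5, 0.1),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic session generators.

    Attributes
    ----------
    seed
        Master seed; identical seeds give byte-identical outputs.
    epoch_s
        Scoring epoch length, seconds.
    eeg_fs, ca_fs, photom_fs, psp_fs
        Sampling rates of the respective modalities (Hz / frames per s).
    state_band_power
        Mapping state -> (delta, theta, broadband, emg) relative power
        weights used by the EEG/EMG generator.
    transition_matrix
        3x3 row-stochastic matrix over (W, N, R) per epoch.
    """

    seed: int = 0
    epoch_s: float = 2.0
    eeg_fs: float = 1000.0
    ca_fs: float = 10.0
    photom_fs: float = 100.0
    psp_fs: float = 10000.0
    eeg_amp_uv: float = 100.0
    emg_amp_uv: float = 50.0
    state_band_power: dict[str, tuple[float, float, float, float]] = field(
        default_factory=default_state_band_power
    )
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not float(self.seed) == int(self.seed):
            raise ConfigError("seed must be an integer")
        for name in ("epoch_s", "eeg_fs", "ca_fs", "photom_fs", "psp_fs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        P = self.transition_matrix
        if P.shape != (3, 3):
            raise ConfigError("transition_matrix must be 3x3 over (W, N, R)")
        if np.any(P < 0):
            raise ConfigError("transition_matrix entries must be nonnegative")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError("transition_matrix rows must sum to 1 (within 1e-12)")
        if set(self.state_band_power) != set(STATES):
            raise ConfigError(f"state_band_power must define exactly {STATES}")
        for s, w in self.state_band_power.items():
            if len(w) != 4 or any(x < 0 for x in w):
                raise ConfigError(
                    f"state_band_power[{s!r}] must be 4 nonnegative weights"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the session seed."""
        if stream not in _STREAMS:
            raise ConfigError(f"unknown random stream {stream!r}")
        ss = np.random.SeedSequence(int(self.seed), spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)
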