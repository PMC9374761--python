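"""Scoring chain: spectrogram, features, classification, bouts, relative delta."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sleepphys import synth
from sleepphys.core import Hypnogram, Recording
from sleepphys.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ThresholdEstimationError,
)
from sleepphys.score import (
    Spectrogram,
    Thresholds,
    classify_epochs,
    compute_spectrogram,
    estimate_emg_threshold,
    extract_features,
    relative_delta,
    segment_bouts,
)


def _rec(eeg, fs=1000.0):
    eeg = np.asarray(eeg, dtype=float)
    return Recording(eeg[None, :], np.zeros_like(eeg), fs)


class TestSpectrogram:
    def test_pure_delta_tone_peaks_in_delta_band(self):
        t = np.arange(0, 30, 1e-3)
        spec = compute_spectrogram(_rec(50 * np.sin(2 * np.pi * 2.0 * t)))
        peaks = spec.freqs[np.argmax(spec.power, axis=1)]
        assert np.all((peaks >= 0.5) & (peaks <= 4.0))

    def test_zero_signal_zero_power(self):
        spec = compute_spectrogram(_rec(np.zeros(20_000)))
        assert np.all(spec.power == 0)

    def test_white_noise_satisfies_parseval(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(120_000)
        spec = compute_spectrogram(_rec(x))
        integrated = spec.power.sum(axis=1).mean() * spec.df
        assert integrated == pytest.approx(x.var(), rel=0.05)

    def test_epoch_count_formula(self):
        spec = compute_spectrogram(_rec(np.zeros(13_500)))  # 13.5 s
        assert spec.n_epochs == int((13.5 - 5) // 2) + 1

    def test_too_short_recording_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_spectrogram(_rec(np.zeros(3000)))


class TestFeatures:
    def test_delta_concentrated_spectrum_has_zero_theta_ratio(self):
        freqs = np.arange(0, 26, 0.2)
        power = np.zeros((4, freqs.size))
        power[:, (freqs >= 1) & (freqs <= 3)] = 5.0
        spec = Spectrogram(np.arange(4) * 2.0, freqs, power)
        rec = _rec(np.zeros(13_000))
        feats = extract_features(spec, rec)
        assert np.all(feats["theta_power"] == 0)
        assert np.all(feats["theta_delta_ratio"] == 0)

    def test_constant_emg_rms_is_abs_value(self):
        t = np.arange(0, 13, 1e-3)
        rec = Recording(np.zeros((1, t.size)), np.full(t.size, -3.0), 1000.0)
        spec = compute_spectrogram(rec)
        feats = extract_features(spec, rec, emg_band=None)
        assert np.allclose(feats["emg_rms"], 3.0)

    def test_synthetic_nrem_has_higher_relative_delta_than_wake(self, cfg, short_session):
        hyp, rec = short_session
        spec = compute_spectrogram(rec)
        feats = extract_features(spec, rec)
        frac = feats["delta_power"] / feats["total_power"]
        st = hyp.states[: spec.n_epochs]
        assert np.median(frac[st == "N"]) > np.median(frac[st == "W"])


class TestClassification:
    def _features(self, emg, ratio):
        n = len(emg)
        return pd.DataFrame(
            {
                "epoch_time_s": np.arange(n) * 2.0,
                "delta_power": np.ones(n),
                "theta_power": np.asarray(ratio, float),
                "theta_delta_ratio": np.asarray(ratio, float),
                "ratio_defined": np.ones(n, bool),
                "total_power": np.ones(n),
                "emg_rms": np.asarray(emg, float),
            }
        )

    def test_rule_assigns_w_n_r(self):
        feats = self._features(emg=[9, 9, 1, 1, 1, 1], ratio=[0.1, 0.1, 0.2, 0.2, 3, 3])
        hyp = classify_epochs(feats, Thresholds(emg_rms=5.0), smooth_islands=False,
                              enforce_wake_to_rem=False)
        assert "".join(hyp.states) == "WWNNRR"

    def test_island_smoothing_and_wake_rem_constraint(self):
        feats = self._features(emg=[1, 1, 9, 1, 1], ratio=[0.1] * 5)
        hyp = classify_epochs(feats, Thresholds(emg_rms=5.0))
        # lone wake island between identical NREM neighbours is smoothed away
        assert "".join(hyp.states) == "NNNNN"
        feats2 = self._features(emg=[9, 9, 1, 1, 1], ratio=[0.1, 0.1, 3.0, 3.0, 3.0])
        hyp2 = classify_epochs(feats2, Thresholds(emg_rms=5.0))
        assert hyp2.states[2] == "W"  # REM cannot directly follow wake

    def test_manual_overrides_applied_last(self):
        feats = self._features(emg=[9, 9, 9, 9], ratio=[0.1] * 4)
        hyp = classify_epochs(feats, Thresholds(emg_rms=5.0), overrides=[(2, "N")])
        assert hyp.states[2] == "N" and hyp.provenance == "manual-corrected"

    def test_constant_features_raise_threshold_error(self):
        with pytest.raises(ThresholdEstimationError):
            estimate_emg_threshold(np.full(100, 2.0))

    def test_scoring_recovers_generating_hypnogram(self, cfg, short_session):
        hyp, rec = short_session
        spec = compute_spectrogram(rec)
        scored = classify_epochs(extract_features(spec, rec))
        acc = np.mean(scored.states == hyp.states[: scored.n_epochs])
        assert acc >= 0.9


class TestBouts:
    def test_run_length_example(self):
        hyp = Hypnogram(np.array(list("WWNNNW")), epoch_s=2.0)
        bouts = segment_bouts(hyp)
        n = bouts[bouts["state"] == "N"].iloc[0]
        assert (n["onset_s"], n["offset_s"], n["duration_s"]) == (4.0, 10.0, 6.0)

    def test_single_state_single_bout(self):
        hyp = Hypnogram(np.array(["R"] * 10), epoch_s=2.0)
        bouts = segment_bouts(hyp)
        assert len(bouts) == 1 and bouts.iloc[0]["duration_s"] == 20.0

    def test_short_run_absorbed_conserving_time(self):
        hyp = Hypnogram(np.array(list("NNNRNNN")), epoch_s=2.0)
        bouts = segment_bouts(hyp, min_bout_s=4.0)
        assert list(bouts["state"]) == ["N"]
        assert bouts["duration_s"].sum() == hyp.duration_s

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.sampled_from("WNR"), min_size=1, max_size=60))
    def test_bout_table_tiles_hypnogram(self, labels):
        hyp = Hypnogram(np.array(labels), epoch_s=2.0)
        bouts = segment_bouts(hyp, min_bout_s=4.0)
        assert bouts.iloc[0]["onset_s"] == 0.0
        assert bouts.iloc[-1]["offset_s"] == hyp.duration_s
        assert np.all(bouts["onset_s"].to_numpy()[1:] == bouts["offset_s"].to_numpy()[:-1])
        assert bouts["duration_s"].sum() == hyp.duration_s


class TestRelativeDelta:
    def test_invariant_to_global_rescaling(self, short_session):
        _, rec = short_session
        spec = compute_spectrogram(rec)
        scaled = Recording(rec.eeg * 3.7, rec.emg, rec.fs)
        spec2 = compute_spectrogram(scaled)
        assert np.allclose(relative_delta(spec), relative_delta(spec2), rtol=1e-12)

    def test_pure_delta_signal_session_mean_is_one(self):
        t = np.arange(0, 120, 1e-3)
        spec = compute_spectrogram(_rec(40 * np.sin(2 * np.pi * 2.0 * t)))
        rd = relative_delta(spec)
        assert rd.mean() == pytest.approx(1.0, abs=0.02)

    def test_zero_power_session_raises(self):
        spec = compute_spectrogram(_rec(np.zeros(10_000)))
        with pytest.raises(DegenerateDataError):
            relative_delta(spec)
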