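"""Closed-loop triggering, probability traces, transition and bout statistics."""

import numpy as np
import pytest

from sleepphys import stim as st
from sleepphys import synth
from sleepphys.config import SimConfig
from sleepphys.core import Hypnogram
from sleepphys.errors import InsufficientDataError, ScheduleError
from sleepphys.score import compute_spectrogram


class TestClosedLoop:
    def test_inactive_indicator_never_triggers(self):
        assert st.simulate_closed_loop(np.zeros(5000, bool), 1.0).size == 0

    def test_continuous_activity_trigger_times(self):
        # 40 min of continuous activity: first trigger when persistence
        # completes (300 s), second as soon as the 30-min spacing allows
        ind = np.ones(2400, bool)
        onsets = st.simulate_closed_loop(ind, 1.0)
        assert list(onsets) == [300.0, 2100.0]

    def test_interrupted_activity_never_reaches_persistence(self):
        # 4-min activity blocks separated by rests: counter always resets
        block = np.r_[np.ones(240, bool), np.zeros(60, bool)]
        ind = np.tile(block, 20)
        assert st.simulate_closed_loop(ind, 1.0).size == 0

    def test_constraints_hold_on_random_inputs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            # blocky random indicator with long dwell times
            ind = np.repeat(rng.random(60) < 0.6, rng.integers(30, 400, 60))
            onsets = st.simulate_closed_loop(ind, 1.0)
            assert np.all(np.diff(onsets) >= 1800.0)
            for on in onsets:
                i = int(on)
                assert np.all(ind[i - 300 : i])  # 5 min of continuous activity


class TestFixedInterval:
    def test_three_hours_of_45min_intervals(self):
        assert list(st.fixed_interval_onsets(3 * 3600) / 60) == [0, 45, 90, 135]

    def test_short_span_single_onset(self):
        assert list(st.fixed_interval_onsets(1000.0)) == [0.0]

    def test_consistent_with_schedule_generator(self):
        sched = synth.gen_schedule("fixed_interval", span_s=4 * 3600, interval_s=2700, on_s=120)
        assert np.array_equal(
            st.fixed_interval_onsets(4 * 3600), sched["onset_s"].to_numpy()
        )

    def test_bad_interval_rejected(self):
        with pytest.raises(ScheduleError):
            st.fixed_interval_onsets(100.0, interval_s=0.0)


class TestStateProbabilityTrace:
    def test_all_wake_trials_probability_one_ci_zero(self):
        hyp = Hypnogram(np.array(["W"] * 600), epoch_s=2.0)
        trace = st.state_probability_trace(hyp, [400.0, 500.0, 600.0], seed=0)
        assert np.all(trace.p["W"] == 1.0)
        assert np.all(trace.ci_low["W"] == 1.0) and np.all(trace.ci_high["W"] == 1.0)

    def test_probabilities_partition_to_one(self, cfg):
        hyp = synth.gen_hypnogram(cfg, 1800)
        onsets = np.arange(300.0, 3000.0, 400.0)
        trace = st.state_probability_trace(hyp, onsets, seed=1)
        total = trace.p["W"] + trace.p["N"] + trace.p["R"]
        assert np.allclose(total, 1.0, atol=1e-12)
        for s in "WNR":
            assert np.all(trace.ci_low[s] <= trace.p[s] + 1e-12)
            assert np.all(trace.ci_high[s] >= trace.p[s] - 1e-12)

    def test_no_usable_trials_raises(self):
        hyp = Hypnogram(np.array(["W"] * 100), epoch_s=2.0)
        with pytest.raises(InsufficientDataError):
            st.state_probability_trace(hyp, [10.0])


class TestTransitionProbability:
    def test_nrem_every_trial_probability_one(self):
        # wake at each onset, NREM beginning mid-stimulation
        block = ["W"] * 60 + ["N"] * 60  # 4-min blocks
        hyp = Hypnogram(np.array(block * 5), epoch_s=2.0)
        onsets = np.arange(0.0, 5 * 240.0, 240.0)  # each onset in wake
        trials = st.make_stim_trials(hyp, onsets, duration_s=120.0)
        res = st.transition_probability(trials, hyp)
        assert res.probability == 1.0 and res.n_trials == 5

    def test_wake_throughout_probability_zero(self):
        hyp = Hypnogram(np.array(["W"] * 900), epoch_s=2.0)
        trials = st.make_stim_trials(hyp, [100.0, 500.0, 900.0], duration_s=120.0)
        res = st.transition_probability(trials, hyp)
        assert res.probability == 0.0

    def test_hand_built_seven_of_ten(self):
        # 10 trials spaced 10 min apart; NREM follows the first 7 onsets only
        labels = []
        for k in range(10):
            if k < 7:
                labels += ["W"] * 100 + ["N"] * 100 + ["W"] * 100
            else:
                labels += ["W"] * 300
        hyp = Hypnogram(np.array(labels), epoch_s=2.0)
        onsets = np.arange(0.0, 6000.0, 600.0) + 100.0
        trials = st.make_stim_trials(hyp, onsets, duration_s=60.0)
        res = st.transition_probability(trials, hyp)
        assert res.n_success == 7 and res.n_trials == 10
        assert res.probability == pytest.approx(0.7)

    def test_invariant_to_trial_order_and_matches_recount(self):
        rng = np.random.default_rng(31)
        for trial_seed in range(10):
            c = SimConfig(seed=100 + trial_seed)
            hyp = synth.gen_hypnogram(c, 900)
            onsets = np.sort(rng.uniform(0, hyp.duration_s - 500, 8))
            trials = st.make_stim_trials(hyp, onsets, duration_s=120.0)
            res = st.transition_probability(trials, hyp)
            shuffled = trials.sample(frac=1.0, random_state=1)
            res2 = st.transition_probability(shuffled, hyp)
            assert res.probability == res2.probability
            # brute-force recount from the raw label sequence
            k = n = 0
            for on in onsets:
                if hyp.states[int(on // 2)] != "W":
                    continue
                n += 1
                success = False
                upper = min(int(np.ceil((on + 120 + 300) / 2)), hyp.n_epochs)
                for b in range(int(on // 2), upper):
                    if hyp.states[b] == "N" and (b == 0 or hyp.states[b - 1] != "N"):
                        run = 0
                        while b + run < hyp.n_epochs and hyp.states[b + run] == "N":
                            run += 1
                        if run * 2 >= 30 and b * 2 >= on:
                            success = True
                            break
                k += success
            if n:
                assert res.probability == pytest.approx(k / n)


class TestInducedVsNatural:
    def _session(self, cfg):
        hyp = synth.gen_hypnogram(cfg, 1800)  # 1 h
        rec = synth.gen_eeg_emg(hyp, cfg)
        return hyp, compute_spectrogram(rec)

    def test_hand_built_window_assignment(self):
        # onset at 600 s; first NREM bout at 700 s is induced; the bout at
        # 2000 s (>= 15 min from the onset) is natural; 800-s bout onset is
        # not double-counted
        labels = ["W"] * 350 + ["N"] * 50 + ["W"] * 600 + ["N"] * 100 + ["W"] * 700
        hyp = Hypnogram(np.array(labels), epoch_s=2.0)
        t = np.arange(0, hyp.duration_s, 1e-2)
        from sleepphys.core import Recording

        rec = Recording(np.sin(2 * np.pi * 2 * t)[None, :] , np.zeros(t.size), 100.0)
        spec = compute_spectrogram(rec)
        res = st.induced_vs_natural(hyp, spec, [600.0])
        assert list(res.induced["onset_s"]) == [700.0]
        assert list(res.natural["onset_s"]) == [2000.0]

    def test_nrem_too_close_to_stim_excluded_from_natural(self):
        labels = ["W"] * 400 + ["N"] * 100 + ["W"] * 400
        hyp = Hypnogram(np.array(labels), epoch_s=2.0)
        t = np.arange(0, hyp.duration_s, 1e-2)
        from sleepphys.core import Recording

        rec = Recording(np.sin(2 * np.pi * 2 * t)[None, :], np.zeros(t.size), 100.0)
        spec = compute_spectrogram(rec)
        # NREM bout at 800 s is 40 s after the 760-s onset: induced, and only
        # 40 s from a stimulation, hence excluded from the natural sample
        res = st.induced_vs_natural(hyp, spec, [760.0])
        assert len(res.induced) == 1 and len(res.natural) == 0

    def test_onset_without_nrem_contributes_nothing(self, cfg):
        hyp = Hypnogram(np.array(["W"] * 1000), epoch_s=2.0)
        t = np.arange(0, hyp.duration_s, 1e-2)
        from sleepphys.core import Recording

        rec = Recording(np.sin(2 * np.pi * 2 * t)[None, :], np.zeros(t.size), 100.0)
        res = st.induced_vs_natural(hyp, compute_spectrogram(rec), [100.0])
        assert len(res.induced) == 0
        assert res.duration_test is None
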