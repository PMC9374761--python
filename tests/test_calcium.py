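"""DF/F, deconvolution, state AUC, selectivity, transitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import signal

from sleepphys import calcium as ca
from sleepphys import synth
from sleepphys.core import EventTrain, Hypnogram
from sleepphys.errors import AlignmentError, DegenerateDataError


def _kernel_trace(n, fs, tau, events):
    """Independent construction: AR(1) response to impulses (time, magnitude)."""
    gamma = np.exp(-1.0 / (tau * fs))
    s = np.zeros(n)
    for t, m in events:
        s[int(round(t * fs))] += m
    return signal.lfilter([1.0], [1.0, -gamma], s)


class TestDFF:
    def test_constant_trace_gives_zeros(self):
        assert np.all(ca.compute_dff(np.full(100, 3.5)) == 0)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(0)
        dff = ca.compute_dff(1 + rng.random(1000))
        assert abs(dff.mean()) < 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        f = 1 + rng.random(500)
        assert np.allclose(ca.compute_dff(f), ca.compute_dff(2 * f))

    def test_zero_mean_trace_raises(self):
        with pytest.raises(DegenerateDataError):
            ca.compute_dff(np.array([-1.0, 1.0]))


class TestDetectEvents:
    FS, TAU = 10.0, 1.5

    def test_zero_trace_empty_train(self):
        ev = ca.detect_events(np.zeros(500), self.TAU, self.FS, min_magnitude=0.05)
        assert ev.n_events == 0

    def test_single_noiseless_kernel_recovered(self):
        tr = _kernel_trace(600, self.FS, self.TAU, [(20.0, 2.0)])
        ev = ca.detect_events(tr, self.TAU, self.FS, min_magnitude=0.1)
        assert ev.n_events == 1
        assert ev.times_s[0] == pytest.approx(20.0, abs=1 / self.FS)
        assert ev.magnitudes[0] == pytest.approx(2.0, rel=0.05)

    def test_two_separated_kernels_give_two_events(self):
        tr = _kernel_trace(900, self.FS, self.TAU, [(10.0, 1.0), (10.0 + 8 * self.TAU, 1.5)])
        ev = ca.detect_events(tr, self.TAU, self.FS, min_magnitude=0.1)
        assert ev.n_events == 2

    def test_reconvolution_reconstructs_noiseless_trace(self):
        events = [(5.0, 1.0), (20.0, 0.8), (40.0, 2.5)]
        tr = _kernel_trace(600, self.FS, self.TAU, events)
        ev = ca.detect_events(tr, self.TAU, self.FS, min_magnitude=0.1)
        rec = ca.reconvolve(ev, 600, self.TAU, self.FS)
        rel_l2 = np.linalg.norm(rec - tr) / np.linalg.norm(tr)
        assert rel_l2 <= 0.05


class TestStateAUC:
    def test_arithmetic_example(self):
        # 10 min NREM then 10 min wake; all events in NREM, total magnitude 30
        hyp = Hypnogram(np.array(["N"] * 300 + ["W"] * 300), epoch_s=2.0)
        ev = EventTrain(np.linspace(1, 500, 10), np.full(10, 3.0))
        act = ca.state_auc(ev, hyp)
        assert act.auc_per_min["N"] == pytest.approx(3.0)
        assert act.auc_per_min["W"] == 0.0

    def test_empty_train_all_zero(self):
        hyp = Hypnogram(np.array(list("WNR") * 10), epoch_s=2.0)
        act = ca.state_auc(EventTrain(np.empty(0), np.empty(0)), hyp)
        assert all(v == 0.0 for v in act.auc_per_min.values())

    def test_matches_brute_force_per_epoch_accumulation(self):
        rng = np.random.default_rng(5)
        hyp = Hypnogram(rng.choice(list("WNR"), 200), epoch_s=2.0)
        times = rng.uniform(0, hyp.duration_s - 1e-9, 300)
        mags = rng.exponential(1.0, 300)
        act = ca.state_auc(EventTrain(times, mags), hyp)
        # brute force: walk epochs, accumulate magnitudes falling inside each
        sums = {s: 0.0 for s in "WNR"}
        for e in range(hyp.n_epochs):
            lo, hi = e * 2.0, (e + 1) * 2.0
            sums[hyp.states[e]] += mags[(times >= lo) & (times < hi)].sum()
        for s in "WNR":
            mins = np.sum(hyp.states == s) * 2.0 / 60.0
            expect = sums[s] / mins if mins else np.nan
            if mins:
                assert act.auc_per_min[s] == pytest.approx(expect, abs=1e-12)

    def test_event_outside_span_raises(self):
        hyp = Hypnogram(np.array(["N"] * 10), epoch_s=2.0)
        with pytest.raises(AlignmentError):
            ca.state_auc(EventTrain(np.array([25.0]), np.array([1.0])), hyp)

    def test_conservation_total_magnitude(self):
        rng = np.random.default_rng(9)
        hyp = Hypnogram(rng.choice(list("WNR"), 150), epoch_s=2.0)
        ev = EventTrain(rng.uniform(0, hyp.duration_s - 1e-9, 100), rng.exponential(1, 100))
        act = ca.state_auc(ev, hyp)
        total = sum(
            act.auc_per_min[s] * act.state_minutes[s]
            for s in "WNR"
            if act.state_minutes[s] > 0
        )
        assert total == pytest.approx(ev.total_magnitude, abs=1e-9)


class TestSelectivityIndex:
    @pytest.mark.parametrize(
        "a,b,expect", [(2.0, 2.0, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0), (3.0, 1.0, 0.5)]
    )
    def test_known_values(self, a, b, expect):
        assert ca.selectivity_index(a, b) == expect

    def test_both_zero_is_undefined_not_zero(self):
        assert np.isnan(ca.selectivity_index(0.0, 0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.floats(0, 1e6, allow_nan=False),
        hst.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        ab = ca.selectivity_index(a, b)
        ba = ca.selectivity_index(b, a)
        if a + b == 0:
            assert np.isnan(ab)
        else:
            assert ab == -ba
            assert -1.0 <= ab <= 1.0


class TestClassifyCells:
    def _activity(self, w, n, r, minutes=10.0):
        return ca.StateActivity(
            {"W": w, "N": n, "R": r}, {"W": minutes, "N": minutes, "R": minutes}
        )

    @pytest.mark.parametrize(
        "aucs,expect",
        [
            ((1, 5, 1), "NREM-active"),
            ((1, 1, 5), "REM-active"),
            ((5, 1, 1), "wake-active"),
            ((2, 2, 2), "unclassified"),
        ],
    )
    def test_rule_by_construction(self, aucs, expect):
        res = ca.classify_cells([self._activity(*aucs)])[0]
        assert res.cell_class == expect

    def test_missing_state_flags_unclassifiable(self):
        act = ca.StateActivity(
            {"W": 1.0, "N": 1.0, "R": np.nan}, {"W": 10, "N": 10, "R": 0.0}, {"R"}
        )
        res = ca.classify_cells([act])[0]
        assert res.cell_class == "unclassified" and "missing-state" in res.flags

    def test_simulated_nrem_cells_recovered(self, cfg):
        hyp = synth.gen_hypnogram(cfg, 900)  # 30 min
        prof = synth.make_cell_profiles(10, class_fractions={"N": 1.0})
        traces, _ = synth.gen_calcium(hyp, prof, cfg)
        hits = 0
        for tr in traces.traces:
            ev = ca.detect_events(ca.compute_dff(tr), 1.5, traces.fs)
            res = ca.classify_cells([ca.state_auc(ev, hyp)])[0]
            hits += res.cell_class == "NREM-active"
        assert hits >= 9


class TestTransitionActivity:
    def test_short_flanking_bouts_excluded(self):
        # 20-s wake and NREM episodes flanking the boundary: excluded
        hyp = Hypnogram(np.array(["R"] * 20 + ["W"] * 10 + ["N"] * 10 + ["R"] * 20))
        table, _ = ca.transition_activity(
            EventTrain(np.array([60.0]), np.array([1.0])), hyp
        )
        assert len(table) == 0

    def test_events_only_after_boundary(self):
        hyp = Hypnogram(np.array(["W"] * 30 + ["N"] * 30))  # boundary at 60 s
        ev = EventTrain(np.array([65.0, 70.0]), np.array([1.0, 2.0]))
        table, _ = ca.transition_activity(ev, hyp)
        row = table.iloc[0]
        assert row["pre_auc_per_min"] == 0.0 and row["post_auc_per_min"] > 0.0

    def test_hand_built_window_sums(self):
        hyp = Hypnogram(np.array(["W"] * 30 + ["N"] * 30))  # boundary at 60 s
        ev = EventTrain(np.array([35.0, 55.0, 62.0, 89.0]), np.array([1.0, 2.0, 4.0, 8.0]))
        table, _ = ca.transition_activity(ev, hyp, window_s=30.0)
        row = table.iloc[0]
        # pre window [30, 60): events at 35, 55 -> 3.0; post [60, 90): 4 + 8 = 12
        assert row["pre_auc_per_min"] == pytest.approx(3.0 * 2)  # per-minute (30 s window)
        assert row["post_auc_per_min"] == pytest.approx(12.0 * 2)
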