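"""Metric definitions against hand counts and closed-form values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tremorloop as tl
from tremorloop.evaluation import (
    confusion_metrics,
    fn_episodes,
    matched_tpr_threshold,
    paired_compare,
    suppression_pct,
    trigger_latencies,
)

RATE = 2048.0


class TestConfusionMetrics:
    def test_hand_counted_example(self):
        acc, tpr, fpr, fnr = confusion_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert acc == 75.0
        assert tpr == 100.0
        assert fpr == pytest.approx(100.0 / 3.0)
        assert fnr == 0.0

    def test_perfect_agreement(self):
        acc, tpr, fpr, fnr = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (acc, tpr, fpr, fnr) == (100.0, 100.0, 0.0, 0.0)

    def test_inverted_detection(self):
        acc, tpr, fpr, _ = confusion_metrics([0, 1, 0, 1], [1, 0, 1, 0])
        assert (acc, tpr, fpr) == (0.0, 0.0, 100.0)

    def test_no_positive_truth_errors(self):
        with pytest.raises(tl.TremorLoopError, match="positive"):
            confusion_metrics([0, 1], [0, 0])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        det = rng.integers(0, 2, n).astype(bool)
        tru = rng.integers(0, 2, n).astype(bool)
        if not tru.any():
            tru[0] = True
        acc, tpr, fpr, fnr = confusion_metrics(det, tru)
        # brute force frame counting
        tp = sum(d and t for d, t in zip(det, tru))
        fp = sum(d and not t for d, t in zip(det, tru))
        tn = sum(not d and not t for d, t in zip(det, tru))
        fn = sum(not d and t for d, t in zip(det, tru))
        assert acc == pytest.approx(100.0 * (tp + tn) / n, abs=1e-9)
        assert tpr == pytest.approx(100.0 * tp / (tp + fn), abs=1e-9)
        if fp + tn:
            assert fpr == pytest.approx(100.0 * fp / (fp + tn), abs=1e-9)
        assert tpr + fnr == 100.0


class TestFnEpisodes:
    def test_no_misses_gives_empty_list(self):
        assert fn_episodes(np.ones(10), np.ones(10)) == []

    def test_single_19_frame_gap(self):
        truth = np.ones(40)
        det = np.ones(40)
        det[10:29] = 0
        assert fn_episodes(det, truth) == [pytest.approx(1.9)]

    def test_two_separated_gaps(self):
        truth = np.ones(20)
        det = np.ones(20)
        det[2:5] = 0
        det[10:15] = 0
        assert fn_episodes(det, truth) == [pytest.approx(0.3), pytest.approx(0.5)]

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_durations_sum_equals_missed_positive_time(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        det = rng.integers(0, 2, n)
        tru = rng.integers(0, 2, n)
        eps = fn_episodes(det, tru)
        missed = np.sum((tru == 1) & (det == 0)) * 0.1
        assert sum(eps) == pytest.approx(missed)


class TestTremorPower:
    def _accel(self, x):
        return tl.TimeSeries(np.tile(x, (3, 1)), RATE, ["ACC_X", "ACC_Y", "ACC_Z"], ["g"] * 3)

    def test_power_scales_with_amplitude_squared(self):
        t = np.arange(int(5 * RATE)) / RATE
        p1 = tl.tremor_power(self._accel(0.1 * np.sin(2 * np.pi * 5 * t)))
        p2 = tl.tremor_power(self._accel(0.2 * np.sin(2 * np.pi * 5 * t)))
        assert p2 / p1 == pytest.approx(4.0, rel=0.01)

    def test_white_noise_band_fraction(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, int(60 * RATE)))  # independent axes
        ts = tl.TimeSeries(x, RATE, ["ACC_X", "ACC_Y", "ACC_Z"], ["g"] * 3)
        # flat PSD: band power ≈ total variance × (width / Nyquist)
        p = tl.tremor_power(ts)
        expect = x.var(axis=1).sum() * 4.0 / (RATE / 2)
        assert abs(p - expect) / expect < 0.10

    def test_zero_signal_zero_power(self):
        assert tl.tremor_power(self._accel(np.zeros(int(2 * RATE)))) == 0.0


class TestEnergyIndex:
    def _trace(self, on_frames, n=1000, amp=2.0):
        on = np.zeros(n, bool)
        on[:on_frames] = True
        return tl.ClosedLoopTrace(
            score=np.zeros(n), detection=on.astype(int), stim_on=on,
            amplitude_v=np.where(on, amp, 0.0), tremor_power=np.zeros(n),
            truth_state=np.zeros(n), warmup=np.zeros(n, bool),
        )

    def test_continuous_100s_at_2v_gives_6_24(self):
        stim = tl.StimParams(amplitude_v=2.0)
        trace = self._trace(1000)  # 100 s all on
        assert tl.energy_index(trace, stim) == pytest.approx(
            2.0**2 * 130.0 * 120e-6 * 100.0
        )

    def test_half_duty_cycle_halves_energy(self):
        stim = tl.StimParams(amplitude_v=2.0)
        assert tl.energy_index(self._trace(500), stim) == pytest.approx(
            0.5 * tl.energy_index(self._trace(1000), stim)
        )

    def test_suppression_edge_cases(self):
        assert suppression_pct(1.0, 1.0) == 0.0
        with pytest.raises(tl.TremorLoopError, match="suppression|zero"):
            suppression_pct(1.0, 0.0)


class TestPairedCompare:
    def test_identical_vectors(self):
        t, p = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_offset_is_degenerate(self):
        with pytest.raises(tl.TremorLoopError, match="degenerate|variance"):
            paired_compare(np.arange(6.0) + 2.0, np.arange(6.0))

    def test_closed_form_three_pairs(self):
        # diffs [1, 2, 3]: t = mean / (sd/√n) = 2 / (1/√3) = 2√3
        t, p = paired_compare([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0))


class TestLatency:
    def test_detection_at_onset_gives_zero_latency(self):
        truth = np.r_[np.zeros(5), np.ones(10), np.zeros(5)]
        scores = np.r_[np.zeros(5), np.ones(10), np.zeros(5)]
        assert trigger_latencies(scores, truth, 0.5) == [0.0]

    def test_identical_score_series_give_zero_difference(self):
        rng = np.random.default_rng(1)
        truth = np.r_[np.zeros(10), np.ones(20), np.zeros(10),
                      np.ones(20), np.zeros(10), np.ones(20), np.zeros(10)]
        scores = np.clip(truth * 0.8 + 0.1 * rng.standard_normal(len(truth)), 0, 1)
        out = tl.anticipation_latency(scores, scores, truth, matched_tpr=0.7)
        assert out["latency_difference_s"] == 0.0

    def test_unreachable_tpr_raises(self):
        truth = np.r_[np.zeros(5), np.ones(5)] .astype(bool)
        scores = np.zeros(10)
        thr = matched_tpr_threshold(scores, truth, 0.5)  # all-equal scores reach TPR 1
        assert thr == 0.0
        with pytest.raises(tl.TremorLoopError, match="positive"):
            matched_tpr_threshold(scores, np.zeros(10, bool), 0.5)
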