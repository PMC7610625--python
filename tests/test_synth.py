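"""Generator behaviour: determinism, spectral effects, artifact, dynamics."""

import numpy as np
import pytest
from scipy import signal

import tremorloop as tl
from tremorloop.core import MotorState, frame_boundaries


class TestMakeProtocol:
    def test_paper_style_movement_protocol(self):
        p = tl.make_protocol("movement", 6, 30.0, 30.0)
        moves = [(s, d) for s, d in p.blocks if s == MotorState.MOVE]
        assert len(moves) == 6 and all(d == 30.0 for _, d in moves)
        assert p.blocks[0][0] == MotorState.REST and p.blocks[-1][0] == MotorState.REST

    def test_single_posture_block(self):
        p = tl.make_protocol("posture", 1, 10.0, 10.0)
        assert [s for s, _ in p.blocks] == [MotorState.REST, MotorState.POSTURE, MotorState.REST]

    def test_task_fraction_near_half(self):
        p = tl.make_protocol("posture", 8, 30.0, 30.0)
        task = sum(d for s, d in p.blocks if s != MotorState.REST)
        assert abs(task / p.duration_s - 8 * 30 / (8 * 30 + 9 * 30)) < 1e-9

    def test_invalid_durations(self):
        with pytest.raises(tl.TremorLoopError):
            tl.make_protocol("posture", 2, -1.0, 10.0)


class TestGenerateSession:
    def test_seeded_determinism(self):
        p = tl.make_protocol("posture", 1, 10.0, 10.0)
        a = tl.generate_session(tl.SimConfig(seed=5), p)
        b = tl.generate_session(tl.SimConfig(seed=5), p)
        np.testing.assert_array_equal(a.lfp.samples, b.lfp.samples)
        np.testing.assert_array_equal(a.accel.samples, b.accel.samples)
        np.testing.assert_array_equal(a.emg.samples, b.emg.samples)

    def test_pure_rest_has_no_tremor(self):
        p = tl.SessionProtocol([(MotorState.REST, 30.0)], task="posture")
        s = tl.generate_session(tl.SimConfig(seed=6), p)
        assert np.all(s.truth_states.values == int(MotorState.REST))
        assert np.max(s.truth_tremor_amp.values) == 0.0
        # accel tremor-band power at the white-noise floor
        _, target = tl.tremor_labels(s.accel)
        cfg = tl.SimConfig()
        noise_floor = 3 * cfg.accel_noise_g**2 / (cfg.rate_hz / 2)  # flat PSD level, 3 axes
        assert np.median(target.power[5:]) < 10 * noise_floor * 4.0  # 4 Hz band width

    def test_band_power_modulation_directions(self, posture_session, movement_session):
        """Beta down in task frames; theta up in posture; gamma up in movement."""

        def band_ratio(sess, band, task_state):
            states = sess.truth_states.values
            b = frame_boundaries(sess.lfp.n_samples, sess.lfp.rate_hz)
            rest = np.concatenate(
                [sess.lfp.samples[0, b[k]:b[k + 1]] for k in range(len(states)) if states[k] == 0]
            )
            task = np.concatenate(
                [sess.lfp.samples[0, b[k]:b[k + 1]]
                 for k in range(len(states)) if states[k] == task_state]
            )
            f, pr = signal.welch(rest, fs=2048.0, nperseg=2048)
            f, pt = signal.welch(task, fs=2048.0, nperseg=2048)
            sel = (f >= band[0]) & (f <= band[1])
            return pt[sel].mean() / pr[sel].mean()

        post, _ = posture_session
        move, _ = movement_session
        assert band_ratio(post, (13, 30), 2) < 1.0
        assert band_ratio(post, (4, 7), 2) > 1.0
        assert band_ratio(move, (13, 30), 1) < 1.0
        assert band_ratio(move, (55, 95), 1) > 1.0

    def test_emg_envelope_higher_in_task(self, posture_session):
        s, _ = posture_session
        states = s.truth_states.values
        b = frame_boundaries(s.emg.n_samples, s.emg.rate_hz)
        env = np.array([np.sqrt(np.mean(s.emg.samples[0, b[k]:b[k + 1]] ** 2))
                        for k in range(len(states))])
        assert env[states != 0].mean() > env[states == 0].mean()

    def test_schedule_length_mismatch(self):
        p = tl.make_protocol("posture", 1, 10.0, 10.0)
        with pytest.raises(tl.TremorLoopError, match="schedule"):
            tl.generate_session(tl.SimConfig(), p, stim_schedule=np.ones(7, bool))


class TestTremorDynamics:
    def test_steady_state_suppression_ratio(self):
        """Stim held on: steady tremor amplitude → (1−s) × unstimulated level."""
        cfg = tl.SimConfig(seed=7)
        hold = 10.0 * cfg.stim_tau_s + cfg.tremor_onset_delay_s + 5 * cfg.tremor_rise_tau_s
        p = tl.SessionProtocol([(MotorState.POSTURE, float(np.ceil(hold)))], task="posture")
        nf = tl.n_frames_for(p.duration_s)
        off = tl.generate_session(cfg, p, stim_schedule=np.zeros(nf, bool))
        on = tl.generate_session(cfg, p, stim_schedule=np.ones(nf, bool))
        ratio = on.truth_tremor_amp.values[-1] / off.truth_tremor_amp.values[-1]
        expected = 1.0 - cfg.stim_suppression_fraction
        assert abs(ratio - expected) / expected < 0.02

    def test_onset_delay_respected(self, posture_session):
        s, p = posture_session
        labels, _ = tl.tremor_labels(s.accel)
        onset_frame = 200  # first posture block starts at 20 s
        first = np.flatnonzero(labels.labels[onset_frame:])
        assert len(first) and first[0] >= 40  # ≥ 4 s after posture onset


class TestStimArtifact:
    def _rest_lfp(self, dur=30.0, seed=8):
        p = tl.SessionProtocol([(MotorState.REST, dur)], task="posture")
        return tl.generate_session(tl.SimConfig(seed=seed), p).lfp

    def test_zero_gain_is_identity(self):
        lfp = self._rest_lfp(5.0)
        on = tl.FrameSeries(np.ones(50))
        out = tl.inject_stim_artifact(lfp, on, artifact_gain=0.0)
        np.testing.assert_array_equal(out.samples, lfp.samples)

    def test_off_frames_unchanged(self):
        lfp = self._rest_lfp(5.0)
        on = tl.FrameSeries(np.r_[np.zeros(20), np.ones(10), np.zeros(20)])
        out = tl.inject_stim_artifact(lfp, on)
        b = frame_boundaries(lfp.n_samples, lfp.rate_hz)
        np.testing.assert_array_equal(out.samples[:, : b[20]], lfp.samples[:, : b[20]])
        np.testing.assert_array_equal(out.samples[:, b[30]:], lfp.samples[:, b[30]:])
        assert not np.array_equal(out.samples[:, b[20]:b[30]], lfp.samples[:, b[20]:b[30]])

    def test_dominant_high_frequency_peak_at_stim_frequency(self):
        lfp = self._rest_lfp(30.0)
        out = tl.inject_stim_artifact(lfp, tl.FrameSeries(np.ones(300)))
        f, p = signal.welch(out.samples[0], fs=2048.0, nperseg=2048, noverlap=1024, window="hann")
        above = f > 100
        assert f[above][np.argmax(p[above])] == pytest.approx(130.0, abs=1.0)

    def test_fold_back_matches_analytic_aliasing_formula(self):
        """Harmonics k·130 above Nyquist appear at |2048·round(k·130/2048) − k·130|."""
        zeros = tl.TimeSeries(np.zeros((1, int(30 * 2048))), 2048.0, ["LFP_01"], ["uV"])
        out = tl.inject_stim_artifact(zeros, tl.FrameSeries(np.ones(300)))
        f, p = signal.welch(out.samples[0], fs=2048.0, nperseg=2048, noverlap=1024, window="hann")
        found = 0
        for k in range(8, 16):
            fa = abs(2048.0 * round(k * 130.0 / 2048.0) - k * 130.0)
            i = int(np.argmin(np.abs(f - fa)))
            lo, hi = max(0, i - 15), i + 16
            neighborhood = np.delete(p[lo:hi], i - lo)
            if p[i] > 5 * np.median(neighborhood):
                found += 1
        assert found >= 6  # folded energy present at the predicted frequencies
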