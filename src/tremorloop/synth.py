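"""Synthetic closed-loop DBS sessions with ground truth.

No public dataset exists for thalamic essential-tremor recordings of this
kind, so this module generates physiologically structured sessions that
reproduce the phenomenology the decoding and control stack depends on:

* 1/f-background LFP with band-limited oscillations whose amplitudes are
  state-modulated — beta (13–30 Hz) desynchronizes during movement and
  posture, theta (4–7 Hz) rises during posture, gamma (55–95 Hz) rises
  during movement;
* postural/kinetic tremor in the accelerometer: a 3–7 Hz oscillation whose
  amplitude follows first-order dynamics — it grows with time constant
  ``tremor_rise_tau_s`` only after ``tremor_onset_delay_s`` seconds of
  sustained movement/posture, and decays toward
  ``(1 - stim_suppression_fraction)`` of its unstimulated level with time
  constant ``stim_tau_s`` whenever stimulation is on;
* a matching tremor-frequency component in the LFP (thalamic tremor
  cells), which is what makes tremor decodable from LFPs at all;
* EMG with an envelope elevated during movement/posture and modulated at
  the tremor frequency when tremor is present;
* the 130 Hz biphasic stimulation artifact, synthesized on a fine grid,
  shaped by a second-order low-pass standing for the electrode/front-end
  coupling, and decimated to 2048 Hz *without* anti-alias filtering so
  that pulse harmonics above the 1024 Hz Nyquist fold back into the
  recorded band, as observed in real recordings.

Everything is generated frame-by-frame (100 ms) with carried filter and
RNG state, so open-loop generation and closed-loop simulation (where the
controller decides each frame's stimulation state) produce identical
statistics, and sessions are byte-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .core import (
    FRAME_S,
    FrameSeries,
    MotorState,
    SessionProtocol,
    SessionRecording,
    TimeSeries,
    TremorLoopError,
    frame_boundaries,
    n_frames_for,
)

__all__ = [
    "StimParams",
    "SimConfig",
    "make_protocol",
    "SessionSynthesizer",
    "generate_session",
    "inject_stim_artifact",
]


@dataclass
class StimParams:
    """Stimulation waveform: biphasic rectangular pulses.

    Defaults: 130 Hz train of 60 µs biphasic phases separated by a 20 µs
    interphase gap; amplitude 1.95 V (the patient-group mean of the 1–3 V
    clinically effective range).
    """

    freq_hz: float = 130.0
    pulse_us: float = 60.0
    gap_us: float = 20.0
    amplitude_v: float = 1.95

    def __post_init__(self):
        if self.freq_hz <= 0:
            raise TremorLoopError("freq_hz must be > 0", code="invalid-stim")
        if self.pulse_us < 0 or self.gap_us < 0:
            raise TremorLoopError("pulse/gap must be >= 0", code="invalid-stim")
        if self.amplitude_v < 0:
            raise TremorLoopError("amplitude must be >= 0", code="invalid-stim")

    def to_dict(self) -> dict:
        return {
            "freq_hz": self.freq_hz,
            "pulse_us": self.pulse_us,
            "gap_us": self.gap_us,
            "amplitude_v": self.amplitude_v,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimParams":
        return cls(**d)


@dataclass
class SimConfig:
    """Generator parameters.  Amplitudes are RMS in the channel's unit.

    ``snr_scale`` multiplies every state-dependent signal component
    (oscillation amplitudes, tremor, EMG bursts) while leaving the noise
    floors untouched; it is the single knob for effect-size sweeps.
    """

    seed: int = 0
    patient_seed: int = 0  # fixes electrode coupling/gains across sessions of one subject
    rate_hz: float = 2048.0
    lfp_channels: int = 3
    # background
    noise_exponent: float = 1.0  # 0 = white, 1 = pink (mixture in between)
    lfp_noise_uv: float = 5.0
    # state-modulated oscillations
    beta_hz: tuple[float, float] = (13.0, 30.0)
    beta_rest_amp: float = 2.0
    beta_move_attenuation: float = 0.5  # fraction removed during MOVE/POSTURE
    theta_hz: tuple[float, float] = (4.0, 7.0)
    theta_rest_amp: float = 1.0
    theta_posture_gain: float = 2.0
    gamma_hz: tuple[float, float] = (55.0, 95.0)
    gamma_rest_amp: float = 0.5
    gamma_move_gain: float = 2.0
    # tremor dynamics
    tremor_hz: float = 5.0
    tremor_amp_g: float = 0.3
    tremor_onset_delay_s: float = 5.0
    tremor_rise_tau_s: float = 5.0
    tremor_release_tau_s: float = 1.0  # action tremor stops quickly once the limb rests
    tremor_lfp_uv: float = 8.0
    stim_suppression_fraction: float = 0.53
    stim_tau_s: float = 2.0
    # accelerometer
    accel_noise_g: float = 0.02
    move_accel_g: float = 0.3
    move_accel_hz: tuple[float, float] = (0.5, 20.0)
    # EMG
    emg_noise_uv: float = 5.0
    emg_burst_gain: float = 4.0
    # stimulation artifact
    artifact_gain: float = 5.0  # RMS µV of the artifact when stim is on
    artifact_shape_hz: float = 150.0
    artifact_oversample: int = 25
    # envelope smoothing of state transitions
    amp_smooth_tau_s: float = 0.2
    snr_scale: float = 1.0

    def __post_init__(self):
        if not 0 <= self.beta_move_attenuation <= 1:
            raise TremorLoopError("beta_move_attenuation must be in [0,1]", code="invalid-config")
        if not 0 <= self.stim_suppression_fraction <= 1:
            raise TremorLoopError("suppression fraction must be in [0,1]", code="invalid-config")
        if not 3 <= self.tremor_hz <= 7:
            raise TremorLoopError("tremor_hz must lie in [3,7]", code="invalid-config")
        if min(self.tremor_onset_delay_s, self.tremor_rise_tau_s, self.stim_tau_s) < 0:
            raise TremorLoopError("delays and taus must be >= 0", code="invalid-config")
        if self.theta_posture_gain < 1 or self.gamma_move_gain < 1:
            raise TremorLoopError("band gains must be >= 1", code="invalid-config")
        if self.lfp_channels < 1:
            raise TremorLoopError("need >= 1 LFP channel", code="invalid-config")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in ("beta_hz", "theta_hz", "gamma_hz", "move_accel_hz"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("beta_hz", "theta_hz", "gamma_hz", "move_accel_hz"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def make_protocol(
    task: str, n_blocks: int, task_s: float = 30.0, rest_s: float = 30.0
) -> SessionProtocol:
    """Alternating REST/task block structure, starting and ending with REST."""
    if n_blocks < 1:
        raise TremorLoopError("need >= 1 task block", code="invalid-protocol")
    if task_s <= 0 or rest_s <= 0:
        raise TremorLoopError("durations must be > 0", code="invalid-protocol")
    state = MotorState.MOVE if task == "movement" else MotorState.POSTURE
    if task not in ("movement", "posture"):
        raise TremorLoopError(f"unknown task {task!r}", code="invalid-protocol")
    blocks: list[tuple[MotorState, float]] = [(MotorState.REST, rest_s)]
    for _ in range(n_blocks):
        blocks.append((state, task_s))
        blocks.append((MotorState.REST, rest_s))
    return SessionProtocol(blocks=blocks, task=task)


# ------------------------------------------------------------------ artifact


def _pulse_value(phase_s: np.ndarray, stim: StimParams) -> np.ndarray:
    """Biphasic rectangular waveform value at phase (s into the period)."""
    p = stim.pulse_us * 1e-6
    g = stim.gap_us * 1e-6
    out = np.zeros_like(phase_s)
    out[(phase_s >= 0) & (phase_s < p)] = 1.0
    out[(phase_s >= p + g) & (phase_s < 2 * p + g)] = -1.0
    return out


class _ArtifactEngine:
    """Fine-grid pulse synthesis, shaping and anti-alias-free decimation."""

    def __init__(self, stim: StimParams, rate_hz: float, shape_hz: float, oversample: int):
        self.stim = stim
        self.rate = rate_hz
        self.over = int(oversample)
        if self.over < 20:
            raise TremorLoopError("oversample factor must be >= 20", code="invalid-config")
        self.fine_rate = rate_hz * self.over
        self.sos = _sig.butter(2, shape_hz, fs=self.fine_rate, output="sos")
        self.zi = np.zeros((self.sos.shape[0], 2))
        self.unit_rms = self._calibrate()

    def _calibrate(self) -> float:
        """RMS of the shaped, decimated all-on train over 1 s steady state."""
        n = int(2 * self.rate)
        fine_t = np.arange(n * self.over) / self.fine_rate
        rect = _pulse_value(np.mod(fine_t, 1.0 / self.stim.freq_hz), self.stim)
        shaped = _sig.sosfilt(self.sos, rect)
        dec = shaped[:: self.over]
        tail = dec[n // 2 :]
        rms = float(np.sqrt(np.mean(tail**2)))
        return rms if rms > 0 else 1.0

    def chunk(self, start_sample: int, n_samples: int, on: bool) -> np.ndarray:
        """Next ``n_samples`` coarse samples of the unit-RMS artifact.

        The filter state is advanced every call (input gated to zero when
        stimulation is off) so pulse phase stays continuous across frames.
        """
        idx = start_sample * self.over + np.arange(n_samples * self.over)
        fine_t = idx / self.fine_rate
        rect = _pulse_value(np.mod(fine_t, 1.0 / self.stim.freq_hz), self.stim)
        if not on:
            rect = np.zeros_like(rect)
        shaped, self.zi = _sig.sosfilt(self.sos, rect, zi=self.zi)
        out = shaped[:: self.over] / self.unit_rms
        if not on:
            out = np.zeros_like(out)  # stim-off frames carry no artifact
        return out


def inject_stim_artifact(
    lfp: TimeSeries,
    stim_on: FrameSeries,
    stim: StimParams | None = None,
    artifact_gain: float = 50.0,
    shape_hz: float = 150.0,
    oversample: int = 25,
) -> TimeSeries:
    """Add the sampled image of the stimulation pulse train to an LFP.

    The biphasic train is synthesized on a fine grid (``oversample`` times
    the LFP rate), shaped by a 2nd-order low-pass (electrode/front-end
    coupling) and decimated by simple subsampling — deliberately without an
    anti-alias filter, so harmonics above the coarse Nyquist frequency fold
    back to ``|k*f_stim - round(k*f_stim/rate)*rate|``.  The artifact is
    scaled to ``artifact_gain`` RMS (in the LFP's units) and added only
    during stimulation-on frames; stim-off frames are returned unchanged.
    ``artifact_gain = 0`` is the identity.
    """
    stim = stim or StimParams()
    if artifact_gain == 0:
        return TimeSeries(
            lfp.samples.copy(), lfp.rate_hz, list(lfp.channel_labels), list(lfp.units)
        )
    engine = _ArtifactEngine(stim, lfp.rate_hz, shape_hz, oversample)
    bounds = frame_boundaries(lfp.n_samples, lfp.rate_hz, stim_on.frame_s)
    on = np.asarray(stim_on.values) > 0
    out = lfp.samples.copy()
    for k in range(min(len(on), len(bounds) - 1)):
        b0, b1 = bounds[k], bounds[k + 1]
        art = engine.chunk(b0, b1 - b0, bool(on[k]))
        out[:, b0:b1] += artifact_gain * art
    return TimeSeries(out, lfp.rate_hz, list(lfp.channel_labels), list(lfp.units))


# ------------------------------------------------------------------ synthesizer

# classic 1/f ("pink") shaping filter for white input (Paul Kellet's IIR fit)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


class _BandSource:
    """Band-limited unit-RMS noise stream with carried filter state."""

    def __init__(self, band, rate_hz, n_streams, order=4):
        lo, hi = band
        self.sos = _sig.butter(order, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
        self.zi = np.zeros((n_streams, self.sos.shape[0], 2))
        # calibrate the filtered-white-noise RMS once, deterministically
        probe = np.random.default_rng(1234).standard_normal(int(4 * rate_hz))
        ref = _sig.sosfilt(self.sos, probe)
        self.scale = 1.0 / max(float(np.sqrt(np.mean(ref[len(ref) // 2 :] ** 2))), 1e-30)

    def process(self, white: np.ndarray) -> np.ndarray:
        white = np.atleast_2d(white)
        out = np.empty_like(white)
        for i in range(white.shape[0]):
            out[i], self.zi[i] = _sig.sosfilt(self.sos, white[i], zi=self.zi[i])
        return out * self.scale


class _PinkSource:
    def __init__(self, rate_hz, n_streams):
        self.zi = np.zeros((n_streams, max(len(_PINK_A), len(_PINK_B)) - 1))
        probe = np.random.default_rng(4321).standard_normal(int(4 * rate_hz))
        ref = _sig.lfilter(_PINK_B, _PINK_A, probe)
        self.scale = 1.0 / max(float(np.sqrt(np.mean(ref[len(ref) // 2 :] ** 2))), 1e-30)

    def process(self, white: np.ndarray) -> np.ndarray:
        white = np.atleast_2d(white)
        out = np.empty_like(white)
        for i in range(white.shape[0]):
            out[i], self.zi[i] = _sig.lfilter(_PINK_B, _PINK_A, white[i], zi=self.zi[i])
        return out * self.scale


class _OnePole:
    """First-order smoother toward a per-sample target (vectorized)."""

    def __init__(self, tau_s, rate_hz, n_streams, init=0.0):
        self.alpha = 1.0 - math.exp(-1.0 / (tau_s * rate_hz)) if tau_s > 0 else 1.0
        self.state = np.full(n_streams, float(init))

    def process(self, target: np.ndarray) -> np.ndarray:
        target = np.atleast_2d(target)
        b = [self.alpha]
        a = [1.0, -(1.0 - self.alpha)]
        out = np.empty_like(target, dtype=float)
        for i in range(target.shape[0]):
            zi = np.array([(1.0 - self.alpha) * self.state[i]])
            out[i], zf = _sig.lfilter(b, a, target[i], zi=zi)
            self.state[i] = out[i][-1] if target.shape[1] else self.state[i]
        return out


class SessionSynthesizer:
    """Streaming generator: one call to :meth:`step` per 100 ms frame.

    The stimulation state for each frame is supplied by the caller (a fixed
    schedule, or the controller in closed-loop simulation); everything else
    — truth states, tremor dynamics, oscillation envelopes — follows the
    protocol deterministically from the seed.
    """

    def __init__(self, config: SimConfig, protocol: SessionProtocol, stim: StimParams | None = None):
        self.cfg = config
        self.protocol = protocol
        self.stim = stim or StimParams()
        rate = config.rate_hz
        self.rate = rate
        self.n_frames = n_frames_for(protocol.duration_s)
        self.n_samples = int(np.rint(self.n_frames * rate * FRAME_S))
        self.bounds = frame_boundaries(self.n_samples, rate)
        self.rng = np.random.default_rng(config.seed)
        nch = config.lfp_channels

        self.sample_states = protocol.sample_states(rate, self.n_samples)
        self._t_in_task = self._time_in_task()

        self.pink = _PinkSource(rate, nch)
        self.beta = _BandSource(config.beta_hz, rate, nch)
        self.theta = _BandSource(config.theta_hz, rate, nch)
        self.gamma = _BandSource(config.gamma_hz, rate, nch)
        self.move_band = _BandSource(config.move_accel_hz, rate, 3, order=2)

        self.beta_env = _OnePole(config.amp_smooth_tau_s, rate, nch, init=config.beta_rest_amp)
        self.theta_env = _OnePole(config.amp_smooth_tau_s, rate, nch, init=config.theta_rest_amp)
        self.gamma_env = _OnePole(config.amp_smooth_tau_s, rate, nch, init=config.gamma_rest_amp)
        self.move_env = _OnePole(config.amp_smooth_tau_s, rate, 1, init=0.0)
        self.emg_env = _OnePole(config.amp_smooth_tau_s, rate, 1, init=1.0)

        self.artifact = _ArtifactEngine(
            self.stim, rate, config.artifact_shape_hz, config.artifact_oversample
        )
        # per-channel artifact coupling and oscillation gains are properties
        # of the electrodes, constant across sessions of the same subject
        prng = np.random.default_rng(90_000 + config.patient_seed)
        self.art_coupling = prng.uniform(0.5, 1.5, size=nch)
        self.osc_gain = prng.uniform(0.8, 1.2, size=nch)
        u = self.rng.standard_normal(3)
        self.tremor_axis = u / np.linalg.norm(u)
        self.tremor_phase0 = float(self.rng.uniform(0, 2 * np.pi))
        self.tremor_amp = 0.0
        self.frame_idx = 0

    def _time_in_task(self) -> np.ndarray:
        """Seconds spent in the current MOVE/POSTURE run, per sample (0 at rest)."""
        active = self.sample_states != int(MotorState.REST)
        idx = np.arange(self.n_samples)
        last_reset = np.maximum.accumulate(np.where(~active, idx, -1))
        return (idx - last_reset) / self.rate * active

    # -- tremor amplitude dynamics ---------------------------------------

    def _advance_tremor(self, sl: slice, stim_on: bool) -> np.ndarray:
        cfg = self.cfg
        gate = (self._t_in_task[sl] >= cfg.tremor_onset_delay_s) & (
            self.sample_states[sl] != int(MotorState.REST)
        )
        active = self.sample_states[sl] != int(MotorState.REST)
        target = np.where(gate, cfg.tremor_amp_g * cfg.snr_scale, 0.0)
        if stim_on:
            target = target * (1.0 - cfg.stim_suppression_fraction)
        dt = 1.0 / self.rate
        out = np.empty(len(target))
        a = self.tremor_amp
        # piecewise-constant target: exact exponential relaxation per segment
        changes = np.flatnonzero((np.diff(target) != 0) | (np.diff(active.astype(int)) != 0)) + 1
        seg_starts = np.concatenate([[0], changes])
        seg_ends = np.concatenate([changes, [len(target)]])
        for s0, s1 in zip(seg_starts, seg_ends):
            tgt = target[s0]
            if stim_on:
                tau = cfg.stim_tau_s
            elif not active[s0]:
                tau = cfg.tremor_release_tau_s
            else:
                tau = cfg.tremor_rise_tau_s
            tau = max(tau, 1e-6)
            k = np.arange(1, s1 - s0 + 1)
            out[s0:s1] = tgt + (a - tgt) * np.exp(-k * dt / tau)
            a = out[s1 - 1]
        self.tremor_amp = float(a)
        return out

    # -- one frame -------------------------------------------------------

    def step(self, stim_on: bool) -> dict:
        """Generate the next 100 ms frame under the given stimulation state."""
        if self.frame_idx >= self.n_frames:
            raise TremorLoopError("protocol exhausted", code="schedule-mismatch")
        k = self.frame_idx
        b0, b1 = self.bounds[k], self.bounds[k + 1]
        n = b1 - b0
        sl = slice(b0, b1)
        cfg = self.cfg
        nch = cfg.lfp_channels
        states = self.sample_states[sl]
        active = states != int(MotorState.REST)
        posture = states == int(MotorState.POSTURE)
        move = states == int(MotorState.MOVE)

        # fixed draw order and counts, independent of states and stim
        w_pink = self.rng.standard_normal((nch, n))
        w_beta = self.rng.standard_normal((nch, n))
        w_theta = self.rng.standard_normal((nch, n))
        w_gamma = self.rng.standard_normal((nch, n))
        w_move = self.rng.standard_normal((3, n))
        w_acc = self.rng.standard_normal((3, n))
        w_emg = self.rng.standard_normal(n)

        s = cfg.snr_scale
        beta_t = cfg.beta_rest_amp * np.clip(1.0 - cfg.beta_move_attenuation * active * s, 0.0, None)
        theta_t = cfg.theta_rest_amp * (1.0 + (cfg.theta_posture_gain - 1.0) * posture * s)
        gamma_t = cfg.gamma_rest_amp * (1.0 + (cfg.gamma_move_gain - 1.0) * move * s)
        beta_a = self.beta_env.process(np.tile(beta_t, (nch, 1)))
        theta_a = self.theta_env.process(np.tile(theta_t, (nch, 1)))
        gamma_a = self.gamma_env.process(np.tile(gamma_t, (nch, 1)))

        amp = self._advance_tremor(sl, stim_on)
        t = np.arange(b0, b1) / self.rate
        tremor_osc = np.sin(2 * np.pi * cfg.tremor_hz * t + self.tremor_phase0)
        amp_frac = amp / max(cfg.tremor_amp_g, 1e-30)

        noise = cfg.noise_exponent * self.pink.process(w_pink) + (
            1.0 - cfg.noise_exponent
        ) * w_pink
        lfp = cfg.lfp_noise_uv * noise
        lfp += self.osc_gain[:, None] * (
            beta_a * self.beta.process(w_beta)
            + theta_a * self.theta.process(w_theta)
            + gamma_a * self.gamma.process(w_gamma)
        )
        lfp += cfg.tremor_lfp_uv * s * self.osc_gain[:, None] * (amp_frac * tremor_osc)
        art = self.artifact.chunk(b0, n, stim_on)
        lfp += cfg.artifact_gain * self.art_coupling[:, None] * art

        accel = cfg.accel_noise_g * w_acc
        accel += self.tremor_axis[:, None] * (amp * tremor_osc)
        move_env = self.move_env.process(move.astype(float))[0]
        accel += cfg.move_accel_g * s * move_env * self.move_band.process(w_move)

        emg_target = 1.0 + cfg.emg_burst_gain * s * active
        env = self.emg_env.process(emg_target)[0]
        emg = cfg.emg_noise_uv * env * (1.0 + 0.5 * amp_frac * tremor_osc) * w_emg

        self.frame_idx += 1
        return {
            "lfp": lfp,
            "accel": accel,
            "emg": emg[None, :],
            "truth_state": int(states[0]),
            "tremor_amp": float(amp[-1]),
            "stim_on": bool(stim_on),
        }


def generate_session(
    config: SimConfig,
    protocol: SessionProtocol,
    stim: StimParams | None = None,
    stim_schedule: FrameSeries | np.ndarray | None = None,
) -> SessionRecording:
    """Generate a full open-loop session under a fixed stimulation schedule.

    ``stim_schedule`` gives the per-frame stimulation state (boolean or
    amplitude; ``None`` means stimulation off throughout) and must match
    the protocol's frame count.
    """
    stim = stim or StimParams()
    synth = SessionSynthesizer(config, protocol, stim)
    nf = synth.n_frames
    if stim_schedule is None:
        on = np.zeros(nf, dtype=bool)
    else:
        vals = stim_schedule.values if isinstance(stim_schedule, FrameSeries) else stim_schedule
        vals = np.asarray(vals)
        if len(vals) != nf:
            raise TremorLoopError(
                f"schedule length {len(vals)} != protocol frames {nf}", code="schedule-mismatch"
            )
        on = vals > 0 if vals.dtype != bool else vals

    lfp_parts, acc_parts, emg_parts = [], [], []
    truth = np.empty(nf, dtype=np.int64)
    tamp = np.empty(nf)
    for k in range(nf):
        chunk = synth.step(bool(on[k]))
        lfp_parts.append(chunk["lfp"])
        acc_parts.append(chunk["accel"])
        emg_parts.append(chunk["emg"])
        truth[k] = chunk["truth_state"]
        tamp[k] = chunk["tremor_amp"]

    nch = config.lfp_channels
    lfp = TimeSeries(
        np.concatenate(lfp_parts, axis=1),
        config.rate_hz,
        [f"LFP_{i + 1:02d}" for i in range(nch)],
        ["uV"] * nch,
    )
    accel = TimeSeries(
        np.concatenate(acc_parts, axis=1),
        config.rate_hz,
        ["ACC_X", "ACC_Y", "ACC_Z"],
        ["g"] * 3,
    )
    emg = TimeSeries(
        np.concatenate(emg_parts, axis=1), config.rate_hz, ["EMG_R"], ["uV"]
    )
    return SessionRecording(
        lfp=lfp,
        accel=accel,
        emg=emg,
        stim_trace=FrameSeries(np.where(on, stim.amplitude_v, 0.0)),
        truth_states=FrameSeries(truth),
        truth_tremor_amp=FrameSeries(tamp),
        protocol=protocol,
    )
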