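"""Core data carriers for multichannel electrophysiology sessions.

Everything downstream (simulation, decoding, closed-loop control,
evaluation) runs on two time bases:

* the raw sample grid of the amplifier (default 2048 Hz), carried by
  :class:`TimeSeries`;
* the 100 ms controller frame grid (10 Hz update rate), carried by
  :class:`FrameSeries`.

Frames are half-open intervals ``[k*frame_s, (k+1)*frame_s)`` measured in
seconds from session start.  Because 2048 Hz is not an integer multiple of
10 Hz, frame boundaries on the sample grid are defined once, here, by
:func:`frame_boundaries`, and every module uses that definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "TremorLoopError",
    "MotorState",
    "TimeSeries",
    "FrameSeries",
    "SessionProtocol",
    "SessionRecording",
    "n_frames_for",
    "frame_boundaries",
]


class TremorLoopError(ValueError):
    """Base error with a short machine-readable ``code``."""

    code = "error"

    def __init__(self, message: str = "", code: str | None = None):
        if code is not None:
            self.code = code
        super().__init__(f"{message} [{self.code}]" if message else self.code)


class MotorState(IntEnum):
    """Motor state of the participant on the frame grid.

    REST means no voluntary movement and no tremor-provoking posture.
    MOVE is self-paced voluntary movement (pegboard / pouring style tasks);
    POSTURE is a sustained tremor-provoking posture (arms raised).
    """

    REST = 0
    MOVE = 1
    POSTURE = 2


DEFAULT_RATE_HZ = 2048.0
FRAME_S = 0.1


def n_frames_for(duration_s: float, frame_s: float = FRAME_S) -> int:
    """Number of complete 100 ms frames inside ``duration_s`` seconds."""
    return int(math.floor(duration_s / frame_s + 1e-9))


def frame_boundaries(n_samples: int, rate_hz: float, frame_s: float = FRAME_S) -> np.ndarray:
    """Sample indices of frame edges: frame ``k`` owns ``[b[k], b[k+1])``.

    ``b[k] = round(k * rate_hz * frame_s)`` so frames differ by at most one
    sample in length when ``rate_hz * frame_s`` is not an integer
    (204.8 samples at the 2048 Hz / 100 ms defaults).
    """
    n_frames = n_frames_for(n_samples / rate_hz, frame_s)
    k = np.arange(n_frames + 1)
    b = np.rint(k * rate_hz * frame_s).astype(np.int64)
    return b


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel signal (channel-major).

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
    rate_hz : sampling rate in Hz (default 2048).
    channel_labels : one label per channel; role prefixes (``LFP_``,
        ``ACC_``, ``EMG_``) drive channel-role resolution in I/O.
    units : physical unit per channel (µV for LFP/EMG, g for accelerometer).
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    channel_labels: list[str] = field(default_factory=list)
    units: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate_hz <= 0:
            raise TremorLoopError("sampling rate must be positive", code="invalid-rate")
        if not np.all(np.isfinite(self.samples)):
            raise TremorLoopError("samples contain NaN/inf", code="non-finite-samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise TremorLoopError("label count != channel count", code="invalid-labels")
        if not self.units:
            self.units = [""] * self.samples.shape[0]
        if len(self.units) != self.samples.shape[0]:
            raise TremorLoopError("unit count != channel count", code="invalid-units")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class FrameSeries:
    """A value per 100 ms controller frame."""

    values: np.ndarray
    frame_s: float = FRAME_S

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise TremorLoopError("FrameSeries must be 1-D", code="invalid-frames")
        if self.frame_s <= 0:
            raise TremorLoopError("frame_s must be positive", code="invalid-frames")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.frame_s

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_s


@dataclass
class SessionProtocol:
    """Ordered block structure of a recording session.

    ``blocks`` is a list of ``(MotorState, duration_s)`` pairs; ``task``
    names the non-rest activity (``"movement"`` or ``"posture"``).
    """

    blocks: list[tuple[MotorState, float]]
    task: str = "movement"

    def __post_init__(self):
        if self.task not in ("movement", "posture"):
            raise TremorLoopError(f"unknown task {self.task!r}", code="invalid-protocol")
        for state, dur in self.blocks:
            if dur <= 0:
                raise TremorLoopError("block durations must be > 0", code="invalid-protocol")
            MotorState(state)

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def state_at(self, t: float) -> MotorState:
        """Motor state at time ``t`` seconds (last block absorbs the end)."""
        acc = 0.0
        for state, dur in self.blocks:
            acc += dur
            if t < acc - 1e-12:
                return MotorState(state)
        return MotorState(self.blocks[-1][0])

    def frame_states(self, frame_s: float = FRAME_S) -> FrameSeries:
        """Motor state per frame, evaluated at each frame's start time."""
        n = n_frames_for(self.duration_s, frame_s)
        vals = np.array([int(self.state_at(k * frame_s)) for k in range(n)], dtype=np.int64)
        return FrameSeries(vals, frame_s)

    def sample_states(self, rate_hz: float, n_samples: int | None = None) -> np.ndarray:
        """Motor state per raw sample (int array)."""
        if n_samples is None:
            n_samples = int(round(self.duration_s * rate_hz))
        edges = np.cumsum([0.0] + [d for _, d in self.blocks])
        t = np.arange(n_samples) / rate_hz
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.blocks) - 1)
        states = np.array([int(s) for s, _ in self.blocks], dtype=np.int64)
        return states[idx]

    def task_state(self) -> MotorState:
        return MotorState.MOVE if self.task == "movement" else MotorState.POSTURE


@dataclass
class SessionRecording:
    """Aligned LFP + accelerometer + EMG + stimulation trace.

    ``stim_trace`` holds the stimulation amplitude (V) per frame.
    ``truth_states`` (synthetic sessions only) holds the ground-truth
    :class:`MotorState` per frame, and ``truth_tremor_amp`` the generator's
    internal tremor amplitude (g) per frame.
    """

    lfp: TimeSeries
    accel: TimeSeries | None = None
    emg: TimeSeries | None = None
    stim_trace: FrameSeries | None = None
    truth_states: FrameSeries | None = None
    truth_tremor_amp: FrameSeries | None = None
    protocol: SessionProtocol | None = None

    def __post_init__(self):
        if self.lfp is None or self.lfp.n_samples == 0:
            raise TremorLoopError("session has no LFP samples", code="invalid-session")
        dur = self.lfp.duration_s
        for ts in (self.accel, self.emg):
            if ts is not None and abs(ts.duration_s - dur) > FRAME_S:
                raise TremorLoopError(
                    "constituent series differ by more than one frame", code="invalid-session"
                )
        if self.stim_trace is None:
            self.stim_trace = FrameSeries(np.zeros(n_frames_for(dur)))
        if np.any(np.asarray(self.stim_trace.values) < 0):
            raise TremorLoopError("stimulation amplitudes must be >= 0", code="invalid-session")
        for fs in (self.stim_trace, self.truth_states, self.truth_tremor_amp):
            if fs is not None and len(fs) != n_frames_for(dur):
                raise TremorLoopError(
                    "frame series length must equal floor(duration * 10)",
                    code="invalid-session",
                )

    @property
    def duration_s(self) -> float:
        return self.lfp.duration_s

    @property
    def n_frames(self) -> int:
        return n_frames_for(self.duration_s)

    def stim_on(self) -> np.ndarray:
        """Boolean stimulation-on indicator per frame."""
        return np.asarray(self.stim_trace.values) > 0
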