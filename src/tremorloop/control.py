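"""Real-time decision engine and the closed-loop simulation harness.

The controller is deliberately minimal: every 100 ms the decoder scores
the trailing LFP window, the score is thresholded, and the stimulator
state follows the detection directly — detected → on, not detected → off,
with no debounce or ramping.  Because stimulation changes the signal, the
decoder for frame ``k`` is chosen by the stimulator state of frame
``k − 1`` (the state the hardware was actually in while the window was
recorded).

:func:`run_closed_loop` couples the controller to the synthetic-session
generator frame by frame: each frame is generated under the current
stimulator state, filtered causally, featurized, scored, and the decision
applied to the next frame — so decoding feeds back into tremor dynamics
and artifact content exactly as in the physical loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FRAME_S, FrameSeries, SessionProtocol, SessionRecording, TimeSeries, TremorLoopError
from .decoding import DecoderModel, ModelBundle
from .features import FeatureSpec, frame_features
from .labeling import tremor_band_power
from .preprocess import FilterSpec, StreamingFilter
from .synth import SessionSynthesizer, SimConfig, StimParams


@dataclass
class ControllerConfig:
    """Closed-loop controller settings (10 Hz update, binary amplitude)."""

    update_hz: float = 10.0
    threshold: float = 0.5
    initial_state: str = "off"
    mode: str = "adbs"  # adbs | cdbs | nodbs
    task: str = "posture"
    window_s: float = 0.5

    def __post_init__(self):
        if abs(self.update_hz * FRAME_S - 1.0) > 1e-9:
            raise TremorLoopError("update rate must match the 100 ms frame grid", code="invalid-config")
        if not 0 < self.threshold < 1:
            raise TremorLoopError("threshold must be in (0,1)", code="invalid-config")
        if self.mode not in ("adbs", "cdbs", "nodbs"):
            raise TremorLoopError(f"unknown mode {self.mode!r}", code="invalid-config")
        if self.initial_state not in ("on", "off"):
            raise TremorLoopError("initial_state must be on/off", code="invalid-config")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def controller_step(state: str, detection: int) -> str:
    """Pure stimulator transition: detected → on, not detected → off."""
    return "on" if detection else "off"


def select_model(models: ModelBundle, task: str, stim_state: str) -> DecoderModel:
    """The decoder for the given cell; raises ``incomplete-grid`` if absent."""
    return models.model(task, stim_state)


@dataclass
class ClosedLoopTrace:
    """Per-frame record of one closed-loop run."""

    score: np.ndarray
    detection: np.ndarray
    stim_on: np.ndarray  # state during each frame
    amplitude_v: np.ndarray
    tremor_power: np.ndarray  # 3–7 Hz accel band power per frame
    truth_state: np.ndarray
    warmup: np.ndarray
    frame_s: float = FRAME_S
    session: SessionRecording | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": np.arange(self.n_frames) * self.frame_s,
                "score": self.score,
                "detection": self.detection,
                "stim_on": self.stim_on.astype(int),
                "amplitude_v": self.amplitude_v,
                "tremor_power": self.tremor_power,
                "truth_state": self.truth_state,
                "warmup": self.warmup.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ClosedLoopTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            score=df["score"].to_numpy(),
            detection=df["detection"].to_numpy(),
            stim_on=df["stim_on"].to_numpy().astype(bool),
            amplitude_v=df["amplitude_v"].to_numpy(),
            tremor_power=df["tremor_power"].to_numpy(),
            truth_state=df["truth_state"].to_numpy(),
            warmup=df["warmup"].to_numpy().astype(bool),
        )


def run_closed_loop(
    config: SimConfig,
    protocol: SessionProtocol,
    stim: StimParams,
    models: ModelBundle | None,
    controller: ControllerConfig,
    seed: int | None = None,
    filter_spec: FilterSpec | None = None,
    feature_spec: FeatureSpec | None = None,
) -> ClosedLoopTrace:
    """Simulate the full loop: generate → filter → featurize → score → act.

    In ``cdbs`` mode the stimulator is forced on at every frame and in
    ``nodbs`` forced off (no decoder needed in either); ``adbs`` scores
    each frame with the model matching the previous frame's stimulator
    state and thresholds it.  Warm-up frames score 0 (no detection).
    """
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    if controller.mode == "adbs" and models is None:
        raise TremorLoopError("adbs mode needs a trained bundle", code="incomplete-grid")
    if models is not None:
        for st in ("on", "off"):
            select_model(models, controller.task, st)  # fail fast on missing cells

    synth = SessionSynthesizer(config, protocol, stim)
    fspec = filter_spec or FilterSpec()
    feat_spec = feature_spec or FeatureSpec()
    filt = StreamingFilter(fspec, config.rate_hz, config.lfp_channels)
    window_n = int(round(controller.window_s * config.rate_hz))
    buf = np.zeros((config.lfp_channels, 0))

    nf = synth.n_frames
    score = np.zeros(nf)
    detection = np.zeros(nf, dtype=int)
    stim_on = np.zeros(nf, dtype=bool)
    truth = np.zeros(nf, dtype=np.int64)
    warm = np.zeros(nf, dtype=bool)
    lfp_parts, acc_parts, emg_parts = [], [], []
    tamp = np.zeros(nf)

    state = controller.initial_state
    if controller.mode == "cdbs":
        state = "on"
    elif controller.mode == "nodbs":
        state = "off"

    seen = 0
    for k in range(nf):
        stim_on[k] = state == "on"
        chunk = synth.step(stim_on[k])
        lfp_parts.append(chunk["lfp"])
        acc_parts.append(chunk["accel"])
        emg_parts.append(chunk["emg"])
        truth[k] = chunk["truth_state"]
        tamp[k] = chunk["tremor_amp"]

        filtered = filt.process(chunk["lfp"])
        seen += filtered.shape[1]
        buf = np.concatenate([buf, filtered], axis=1)[:, -window_n:]
        warm[k] = seen < window_n

        if controller.mode == "cdbs":
            detection[k], state = 1, "on"
            continue
        if controller.mode == "nodbs":
            detection[k], state = 0, "off"
            continue
        if warm[k]:
            detection[k] = 0
        else:
            model = select_model(models, controller.task, "on" if stim_on[k] else "off")
            vec = frame_features(buf, config.rate_hz, feat_spec)
            score[k] = float(model.predict_score(vec[None, :])[0])
            detection[k] = int(score[k] >= controller.threshold)
        state = controller_step(state, detection[k])

    lfp = TimeSeries(
        np.concatenate(lfp_parts, axis=1),
        config.rate_hz,
        [f"LFP_{i + 1:02d}" for i in range(config.lfp_channels)],
        ["uV"] * config.lfp_channels,
    )
    accel = TimeSeries(
        np.concatenate(acc_parts, axis=1), config.rate_hz, ["ACC_X", "ACC_Y", "ACC_Z"], ["g"] * 3
    )
    emg = TimeSeries(np.concatenate(emg_parts, axis=1), config.rate_hz, ["EMG_R"], ["uV"])
    session = SessionRecording(
        lfp=lfp,
        accel=accel,
        emg=emg,
        stim_trace=FrameSeries(np.where(stim_on, stim.amplitude_v, 0.0)),
        truth_states=FrameSeries(truth),
        truth_tremor_amp=FrameSeries(tamp),
        protocol=protocol,
    )
    tremor_power, _ = tremor_band_power(accel, controller.window_s)
    return ClosedLoopTrace(
        score=score,
        detection=detection,
        stim_on=stim_on,
        amplitude_v=np.where(stim_on, stim.amplitude_v, 0.0),
        tremor_power=tremor_power,
        truth_state=truth,
        warmup=warm,
        session=session,
    )
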