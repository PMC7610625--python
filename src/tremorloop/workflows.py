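"""High-level convenience pipelines composing the library stages.

These are the workflows a user runs end to end: featurize a session the
way the online system does, build the four training cells from synthetic
sessions, and train the per-subject model bundle.
"""

from __future__ import annotations

import numpy as np

from .core import FrameSeries, SessionRecording, n_frames_for
from .decoding import ALGORITHMS, ModelBundle, blocks_from_protocol, select_models
from .features import FeatureMatrix, FeatureSpec, extract_features
from .labeling import movement_labels
from .preprocess import FilterSpec, bandpass_causal, frame_signal
from .synth import SimConfig, StimParams, generate_session, make_protocol


def featurize_session(
    session: SessionRecording,
    filter_spec: FilterSpec | None = None,
    feature_spec: FeatureSpec | None = None,
    window_s: float = 0.5,
) -> FeatureMatrix:
    """Causal band-pass → trailing-window framing → 12-feature extraction."""
    filtered = bandpass_causal(session.lfp, filter_spec or FilterSpec())
    return extract_features(frame_signal(filtered, window_s=window_s), feature_spec)


def build_training_cell(
    config: SimConfig,
    task: str,
    stim_state: str,
    stim: StimParams | None = None,
    n_blocks: int = 5,
    task_s: float = 20.0,
    rest_s: float = 20.0,
    seed_offset: int = 0,
) -> dict:
    """Generate one training session and package it as a decoder cell.

    The session runs entirely with stimulation on or off (how training
    data were collected: separate blocks with and without continuous DBS);
    labels come from the EMG total activity.
    """
    stim = stim or StimParams()
    protocol = make_protocol(task, n_blocks, task_s, rest_s)
    nf = n_frames_for(protocol.duration_s)
    schedule = FrameSeries(np.full(nf, stim_state == "on", dtype=bool))
    cfg = SimConfig.from_dict({**config.to_dict(), "seed": config.seed + seed_offset})
    session = generate_session(cfg, protocol, stim, schedule)
    feats = featurize_session(session)
    labels = movement_labels(session.emg, task=task)
    return {
        "features": feats,
        "labels": labels,
        "block_ids": blocks_from_protocol(protocol, feats.n_frames),
        "stim_on": session.stim_on(),
        "session": session,
    }


def train_default_bundle(
    config: SimConfig,
    stim: StimParams | None = None,
    algorithms=("svm", "lr", "lda"),
    k: int = 5,
    seed: int = 0,
    **cell_kwargs,
):
    """Train the four (task × stim-state) models on fresh synthetic sessions."""
    cells = {}
    offset = 0
    for task in ("movement", "posture"):
        for stim_state in ("on", "off"):
            offset += 101
            cells[(task, stim_state)] = build_training_cell(
                config, task, stim_state, stim, seed_offset=offset, **cell_kwargs
            )
    bundle, table = select_models(cells, algorithms=algorithms, k=k, seed=seed)
    return bundle, table, cells
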