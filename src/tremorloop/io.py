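"""Session, config and report I/O.

Two on-disk session formats share one naming scheme built on a base path:

* ``table``:  ``<base>.signals.tsv`` (wide TSV, column 1 = time in
  seconds, one named column per channel) plus ``<base>.frames.tsv``
  (frame-grid traces: stimulation amplitude, ground truth when present)
  and ``<base>.protocol.yaml``.  Lossless for finite doubles.
* ``edf``:    ``<base>.edf`` holding the raw signals at their native rates
  and the frame-grid traces as 10 Hz EDF signals (16-bit quantized).

Channel roles are resolved from label prefixes: ``LFP_``, ``ACC_``,
``EMG_``, ``STIM_``, ``TRUTH_`` (case-insensitive).
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    FrameSeries,
    MotorState,
    SessionProtocol,
    SessionRecording,
    TimeSeries,
    TremorLoopError,
    n_frames_for,
)
from .edf import EdfSignal, read_edf, write_edf

ROLE_PREFIXES = {"lfp": "LFP_", "accel": "ACC_", "emg": "EMG_"}
_UNIT_FOR_ROLE = {"lfp": "uV", "accel": "g", "emg": "uV"}


def resolve_roles(labels: list[str]) -> dict[str, list[int]]:
    """Map channel-role names to channel indices by label prefix."""
    roles: dict[str, list[int]] = {r: [] for r in ROLE_PREFIXES}
    for i, lab in enumerate(labels):
        up = lab.upper()
        for role, pref in ROLE_PREFIXES.items():
            if up.startswith(pref):
                roles[role].append(i)
    return roles


def _with(base: Path, suffix: str) -> Path:
    return Path(str(base) + suffix)


def _base(path) -> Path:
    p = Path(path)
    for suffix in (".signals.tsv", ".frames.tsv", ".protocol.yaml", ".edf"):
        if str(p).endswith(suffix):
            return Path(str(p)[: -len(suffix)])
    return p


# ---------------------------------------------------------------- sessions


def write_session(session: SessionRecording, path, format: str = "table") -> None:
    """Write a session; ``format`` is ``"table"`` (lossless TSV) or ``"edf"``."""
    base = _base(path)
    series = [("lfp", session.lfp), ("accel", session.accel), ("emg", session.emg)]
    series = [(r, ts) for r, ts in series if ts is not None and ts.n_samples > 0]
    labels = [lab for _, ts in series for lab in ts.channel_labels]
    if len(set(labels)) != len(labels):
        raise TremorLoopError("duplicate channel labels", code="invalid-session")
    rates = {ts.rate_hz for _, ts in series}
    if len(rates) != 1:
        raise TremorLoopError("constituent rates differ", code="rate-mismatch")
    rate = rates.pop()
    if session.lfp.n_samples == 0:
        raise TremorLoopError("zero-length session", code="invalid-session")

    if format == "table":
        n = min(ts.n_samples for _, ts in series)
        cols = {"time_s": np.arange(n) / rate}
        for _, ts in series:
            for lab, row in zip(ts.channel_labels, ts.samples):
                cols[lab] = row[:n]
        df = pd.DataFrame(cols)
        df.to_csv(_with(base, ".signals.tsv"), sep="\t", index=False, float_format="%.17g")
        _write_frames_tsv(session, _with(base, ".frames.tsv"))
    elif format == "edf":
        sigs = [
            EdfSignal(label=lab, rate_hz=rate, samples=row, unit=u)
            for _, ts in series
            for lab, row, u in zip(ts.channel_labels, ts.samples, ts.units)
        ]
        sigs.append(
            EdfSignal("STIM_AMP", 10.0, np.asarray(session.stim_trace.values, float), "V")
        )
        if session.truth_states is not None:
            sigs.append(
                EdfSignal(
                    "TRUTH_STATE",
                    10.0,
                    np.asarray(session.truth_states.values, float),
                    "",
                    phys_min=-8.0,
                    phys_max=8.0,
                )
            )
        write_edf(_with(base, ".edf"), sigs)
    else:
        raise TremorLoopError(f"unknown format {format!r}", code="invalid-session")

    if session.protocol is not None:
        save_protocol(session.protocol, _with(base, ".protocol.yaml"))


def _write_frames_tsv(session: SessionRecording, path) -> None:
    cols = {
        "frame_time_s": session.stim_trace.times(),
        "STIM_AMP": np.asarray(session.stim_trace.values, float),
    }
    if session.truth_states is not None:
        cols["TRUTH_STATE"] = np.asarray(session.truth_states.values)
    if session.truth_tremor_amp is not None:
        cols["TRUTH_TREMOR_AMP"] = np.asarray(session.truth_tremor_amp.values, float)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_session(path, format: str = "table", require=("lfp",)) -> SessionRecording:
    """Read a session written by :func:`write_session`.

    ``require`` lists the roles that must be present (default only LFP, as
    in deployment where no external sensors exist); a missing required role
    raises a ``role-missing`` error.
    """
    base = _base(path)
    if format == "table":
        sig_path = _with(base, ".signals.tsv")
        if not sig_path.exists():
            raise TremorLoopError(f"missing {sig_path}", code="file-missing")
        df = pd.read_csv(sig_path, sep="\t", float_precision="round_trip")
        t = df.iloc[:, 0].to_numpy()
        if len(t) < 2:
            raise TremorLoopError("zero-length session", code="invalid-session")
        rate = 1.0 / float(np.median(np.diff(t)))
        rate = round(rate, 6)
        labels = list(df.columns[1:])
        data = df.iloc[:, 1:].to_numpy().T
        stim, truth, tamp = _read_frames_tsv(_with(base, ".frames.tsv"))
    elif format == "edf":
        sigs = read_edf(_with(base, ".edf"))
        frame_sigs = {s.label.upper(): s for s in sigs if s.rate_hz == 10.0}
        raw = [s for s in sigs if s.rate_hz != 10.0]
        if not raw:
            raise TremorLoopError("EDF holds no raw signals", code="invalid-session")
        rates = {s.rate_hz for s in raw}
        if len(rates) != 1:
            raise TremorLoopError("mixed raw rates in EDF", code="rate-mismatch")
        rate = rates.pop()
        labels = [s.label for s in raw]
        data = np.vstack([s.samples for s in raw])
        stim = frame_sigs.get("STIM_AMP")
        stim = FrameSeries(np.asarray(stim.samples, float)) if stim else None
        truth = frame_sigs.get("TRUTH_STATE")
        truth = FrameSeries(np.rint(truth.samples).astype(int)) if truth else None
        tamp = None
    else:
        raise TremorLoopError(f"unknown format {format!r}", code="invalid-session")

    roles = resolve_roles(labels)
    for role in require:
        if not roles.get(role):
            raise TremorLoopError(f"no channels for role {role!r}", code="role-missing")

    def pick(role):
        idx = roles[role]
        if not idx:
            return None
        return TimeSeries(
            data[idx],
            rate,
            [labels[i] for i in idx],
            [_UNIT_FOR_ROLE[role]] * len(idx),
        )

    nf = n_frames_for(data.shape[1] / rate)
    if stim is not None and len(stim) > nf:
        stim = FrameSeries(stim.values[:nf])
    if truth is not None and len(truth) > nf:
        truth = FrameSeries(truth.values[:nf])
    protocol = None
    proto_path = _with(base, ".protocol.yaml")
    if proto_path.exists():
        protocol = load_protocol(proto_path)
    return SessionRecording(
        lfp=pick("lfp"),
        accel=pick("accel"),
        emg=pick("emg"),
        stim_trace=stim,
        truth_states=truth,
        truth_tremor_amp=tamp,
        protocol=protocol,
    )


def _read_frames_tsv(path):
    if not Path(path).exists():
        return None, None, None
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    stim = FrameSeries(df["STIM_AMP"].to_numpy()) if "STIM_AMP" in df else None
    truth = (
        FrameSeries(df["TRUTH_STATE"].to_numpy().astype(int)) if "TRUTH_STATE" in df else None
    )
    tamp = (
        FrameSeries(df["TRUTH_TREMOR_AMP"].to_numpy()) if "TRUTH_TREMOR_AMP" in df else None
    )
    return stim, truth, tamp


# ---------------------------------------------------------------- protocol / config


def save_protocol(protocol: SessionProtocol, path) -> None:
    doc = {
        "task": protocol.task,
        "blocks": [[MotorState(s).name, float(d)] for s, d in protocol.blocks],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_protocol(path) -> SessionProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = [(MotorState[name], float(d)) for name, d in doc["blocks"]]
    return SessionProtocol(blocks=blocks, task=doc.get("task", "movement"))


def save_config(obj, path) -> None:
    """Serialize any dataclass-style config with ``to_dict`` to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(obj.to_dict(), fh)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_report(report: dict, path) -> None:
    """Write a metrics report as JSON."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
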