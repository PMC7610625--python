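"""Minimal European Data Format (EDF) reader/writer.

Implements the plain EDF subset this package needs: continuous recordings,
one-second data records, int16 samples, per-signal sampling rates.  Signals
are quantized to the 16-bit digital range against a per-signal physical
range chosen from the data (symmetric, with 1% headroom), so the round-trip
error is bounded by half a quantization step.

The recording duration must be an integral number of seconds (EDF data
records here are fixed at 1 s); block-structured sessions satisfy this.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

from .core import TremorLoopError

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class EdfSignal:
    label: str
    rate_hz: float  # samples per record (record = 1 s)
    samples: np.ndarray
    unit: str = ""
    phys_min: float | None = None
    phys_max: float | None = None


def _fix(s: str, width: int) -> bytes:
    b = s.encode("ascii", "replace")[:width]
    return b.ljust(width)


def write_edf(path, signals: list[EdfSignal]) -> None:
    """Write a plain EDF file with 1 s records."""
    if not signals:
        raise TremorLoopError("no signals to write", code="invalid-session")
    durations = []
    for s in signals:
        if s.rate_hz <= 0 or s.rate_hz != int(s.rate_hz):
            raise TremorLoopError(
                f"EDF needs an integer per-second rate, got {s.rate_hz}", code="invalid-session"
            )
        durations.append(len(s.samples) / s.rate_hz)
    dur = durations[0]
    if any(abs(d - dur) > 1e-9 for d in durations):
        raise TremorLoopError("signals have different durations", code="invalid-session")
    if dur <= 0 or abs(dur - round(dur)) > 1e-9:
        raise TremorLoopError(
            "EDF export needs a whole number of seconds", code="invalid-session"
        )
    n_records = int(round(dur))
    ns = len(signals)

    headers = []
    scaled = []
    for s in signals:
        x = np.asarray(s.samples, dtype=np.float64)
        if s.phys_min is None or s.phys_max is None:
            amp = float(np.max(np.abs(x))) if x.size else 1.0
            amp = amp * 1.01 if amp > 0 else 1.0
            pmin, pmax = -amp, amp
        else:
            pmin, pmax = float(s.phys_min), float(s.phys_max)
        if pmax <= pmin:
            raise TremorLoopError("physical max must exceed min", code="invalid-session")
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.rint((x - pmin) * gain + _DIG_MIN)
        dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
        scaled.append(dig)
        headers.append((s.label, s.unit, pmin, pmax, int(s.rate_hz)))

    now = _dt.datetime(2000, 1, 1)
    hdr = b"".join(
        [
            _fix("0", 8),
            _fix("X X X X", 80),
            _fix("Startdate X X X X", 80),
            _fix(now.strftime("%d.%m.%y"), 8),
            _fix(now.strftime("%H.%M.%S"), 8),
            _fix(str(256 * (1 + ns)), 8),
            _fix("", 44),
            _fix(str(n_records), 8),
            _fix("1", 8),
            _fix(str(ns), 4),
        ]
    )
    hdr += b"".join(_fix(lab, 16) for lab, *_ in headers)
    hdr += b"".join(_fix("", 80) for _ in headers)
    hdr += b"".join(_fix(unit, 8) for _, unit, *_ in headers)
    hdr += b"".join(_fix(f"{pmin:.8g}"[:8], 8) for *_x, pmin, pmax, _r in headers)
    hdr += b"".join(_fix(f"{pmax:.8g}"[:8], 8) for *_x, pmin, pmax, _r in headers)
    hdr += b"".join(_fix(str(_DIG_MIN), 8) for _ in headers)
    hdr += b"".join(_fix(str(_DIG_MAX), 8) for _ in headers)
    hdr += b"".join(_fix("", 80) for _ in headers)
    hdr += b"".join(_fix(str(r), 8) for *_x, r in headers)
    hdr += b"".join(_fix("", 32) for _ in headers)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            for s, dig in zip(signals, scaled):
                spr = int(s.rate_hz)
                fh.write(dig[rec * spr : (rec + 1) * spr].tobytes())


def read_edf(path) -> list[EdfSignal]:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise TremorLoopError("truncated EDF header", code="invalid-session")
        n_records = int(head[236:244].decode().strip())
        record_s = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig_head = fh.read(256 * ns)

        def fields(offset, width):
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        units = fields(96, 8)  # 16+80 bytes per signal before units
        pmins = [float(v) for v in fields(104, 8)]
        pmaxs = [float(v) for v in fields(112, 8)]
        dmins = [int(v) for v in fields(120, 8)]
        dmaxs = [int(v) for v in fields(128, 8)]
        sprs = [int(v) for v in fields(216, 8)]  # after 2*80-byte text fields

        chunks: list[list[np.ndarray]] = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                raw = fh.read(2 * sprs[i])
                chunks[i].append(np.frombuffer(raw, dtype="<i2"))

    out = []
    for i in range(ns):
        dig = np.concatenate(chunks[i]) if chunks[i] else np.zeros(0, dtype="<i2")
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (dig.astype(np.float64) - dmins[i]) * gain + pmins[i]
        out.append(
            EdfSignal(
                label=labels[i],
                rate_hz=sprs[i] / record_s,
                samples=phys,
                unit=units[i],
                phys_min=pmins[i],
                phys_max=pmaxs[i],
            )
        )
    return out
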