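"""Frame labels and tremor-intensity targets from peripheral signals.

Training labels never come from the LFP itself: voluntary-movement frames
are labeled from the total activity of the EMG (or the accelerometer), and
tremor frames from the 3–7 Hz band power of the accelerometer.  Thresholds
are data-driven — an exact 1-D 2-means split on the log envelope/power —
so labels are invariant to overall signal gain, and a 300 ms hysteresis
(3 frames) suppresses single-frame flicker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import FRAME_S, FrameSeries, TimeSeries, TremorLoopError, frame_boundaries
from .features import band_power_integrated
from .preprocess import frame_signal

TREMOR_BAND = (3.0, 7.0)


@dataclass
class LabelSeries:
    """Binary frame labels with their provenance."""

    labels: np.ndarray  # 0/1 per frame
    source: str  # accel | emg | truth
    task: str  # movement | posture | tremor

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(np.int64)
        if not np.all(np.isin(self.labels, (0, 1))):
            raise TremorLoopError("labels must be binary", code="invalid-labels")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TremorTarget:
    """Continuous 3–7 Hz accelerometer band power per frame (g²/Hz units)."""

    power: np.ndarray
    frame_s: float = FRAME_S

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise TremorLoopError("tremor power must be nonnegative", code="invalid-target")


def split_1d_2means(x: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D 2-means: returns (lower center, upper center, threshold).

    Minimizes within-cluster sum of squares over all sorted split points
    (prefix sums — deterministic, no random initialization).  The
    threshold is the midpoint of the two cluster centers.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2:
        raise TremorLoopError("need >= 2 values", code="no-frames")
    csum = np.cumsum(x)
    total = csum[-1]
    i = np.arange(1, n)  # split: left = x[:i], right = x[i:]
    left_mean = csum[:-1] / i
    right_mean = (total - csum[:-1]) / (n - i)
    csq = np.cumsum(x**2)
    ssw = (csq[:-1] - i * left_mean**2) + (csq[-1] - csq[:-1] - (n - i) * right_mean**2)
    best = int(np.argmin(ssw))
    lo, hi = float(left_mean[best]), float(right_mean[best])
    return lo, hi, 0.5 * (lo + hi)


def apply_hysteresis(raw: np.ndarray, min_frames: int = 3) -> np.ndarray:
    """State flips only when >= ``min_frames`` consecutive frames agree."""
    raw = np.asarray(raw).astype(np.int64)
    out = np.empty_like(raw)
    cur = 0
    i = 0
    n = len(raw)
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        if raw[i] != cur and (j - i) >= min_frames:
            cur = int(raw[i])
        out[i:j] = cur
        i = j
    return out


def _threshold_labels(
    log_env: np.ndarray, valid: np.ndarray, min_frames: int = 3
) -> np.ndarray:
    vals = log_env[valid]
    lo, hi, thr = split_1d_2means(vals)
    rng = float(vals.max() - vals.min())
    # a unimodal envelope still splits: require genuinely bimodal contrast
    # (cluster separation well beyond the within-cluster spread)
    below, above = vals[vals <= thr], vals[vals > thr]
    within = 0.5 * (np.std(below) + np.std(above))
    if rng <= 0 or (hi - lo) < 0.01 * rng or (hi - lo) < 3.0 * within:
        warnings.warn("no contrast in envelope; labeling everything 0", stacklevel=3)
        return np.zeros(len(log_env), dtype=np.int64)
    raw = np.where(valid, (log_env > thr).astype(np.int64), 0)
    return np.where(valid, apply_hysteresis(raw, min_frames), 0)


def movement_labels(
    source: TimeSeries,
    task: str = "movement",
    highpass_hz: float = 10.0,
    min_frames: int = 3,
) -> LabelSeries:
    """Binary movement labels from EMG (or accelerometer) total activity.

    Envelope = per-frame RMS of the high-passed, rectified signal (pooled
    over channels); threshold = midpoint of the exact 2-means split of the
    log envelope; 300 ms hysteresis.
    """
    sos = _sig.butter(4, highpass_hz, btype="highpass", fs=source.rate_hz, output="sos")
    filt = np.vstack([_sig.sosfilt(sos, ch) for ch in source.samples])
    rect = np.abs(filt)
    bounds = frame_boundaries(source.n_samples, source.rate_hz)
    n = len(bounds) - 1
    env = np.empty(n)
    for k in range(n):
        seg = rect[:, bounds[k] : bounds[k + 1]]
        env[k] = np.sqrt(np.mean(seg**2))
    # first frames contain the filter transient; treat first 0.5 s as warm-up
    valid = np.arange(n) >= 5
    log_env = np.log(env + 1e-30)
    labels = _threshold_labels(log_env, valid, min_frames)
    src = "emg" if any(l.upper().startswith("EMG") for l in source.channel_labels) else "accel"
    return LabelSeries(labels, source=src, task=task)


def tremor_band_power(accel: TimeSeries, window_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame 3–7 Hz band power (summed over axes) and the warm-up mask.

    Uses the same Hann-periodogram machinery as the LFP band features, on
    the trailing analysis window; axis powers add, which equals the band
    power of the root-sum-of-squares magnitude for independent axes.
    """
    frames = frame_signal(accel, window_s=window_s)
    power = np.zeros(frames.n_frames)
    for k in range(frames.n_frames):
        if frames.warmup[k]:
            continue
        power[k] = float(np.sum(band_power_integrated(frames.window(k), accel.rate_hz, TREMOR_BAND)))
    return power, frames.warmup.copy()


def tremor_labels(
    accel: TimeSeries,
    threshold_quantile: float | None = None,
    window_s: float = 0.5,
    min_frames: int = 3,
) -> tuple[LabelSeries, TremorTarget]:
    """Binary tremor labels and the continuous tremor-power target.

    Labels are 1 where the per-frame 3–7 Hz accelerometer band power is
    above the 2-means threshold on log power (or above the given quantile
    of log power when ``threshold_quantile`` is set).
    """
    power, warmup = tremor_band_power(accel, window_s)
    valid = ~warmup
    log_p = np.log(power + 1e-30)
    if threshold_quantile is not None:
        thr = float(np.quantile(log_p[valid], threshold_quantile))
        raw = np.where(valid, (log_p > thr).astype(np.int64), 0)
        labels = np.where(valid, apply_hysteresis(raw, min_frames), 0)
    else:
        labels = _threshold_labels(log_p, valid, min_frames)
    return (
        LabelSeries(labels, source="accel", task="tremor"),
        TremorTarget(power),
    )
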