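"""Per-frame LFP feature extraction: 12 features per bipolar channel.

Each 100 ms update computes, from the trailing analysis window of every
bipolar LFP channel:

* 8 log band powers — mean Hann-tapered periodogram power in
  3–7 (theta/tremor), 8–12 (alpha), 13–20 / 21–30 (low/high beta),
  31–45 (low gamma), 55–95 (gamma, skipping 50 Hz mains), 105–195 and
  205–395 Hz (high-frequency bands that also carry stimulation-artifact
  energy, which is informative for the stim-on decoders);
* 4 time-domain statistics — RMS, line length, Hjorth mobility and
  Hjorth complexity.

Band powers are logged (with a small epsilon floor) so that features are
roughly Gaussian and an overall gain change shifts rather than rescales
them.  Features from all channels are concatenated column-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .core import FRAME_S, TremorLoopError
from .preprocess import FrameView

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (3, 7),
    (8, 12),
    (13, 20),
    (21, 30),
    (31, 45),
    (55, 95),
    (105, 195),
    (205, 395),
)
TIME_FEATURES = ("rms", "line_length", "hjorth_mobility", "hjorth_complexity")


@dataclass
class FeatureSpec:
    bands_hz: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    log_epsilon: float = 1e-12

    def __post_init__(self):
        self.bands_hz = tuple((float(a), float(b)) for a, b in self.bands_hz)
        for a, b in self.bands_hz:
            if not 0 < a < b:
                raise TremorLoopError(f"bad band ({a}, {b})", code="band-out-of-range")

    @property
    def n_features(self) -> int:
        return len(self.bands_hz) + len(TIME_FEATURES)

    def names(self, channel_labels: list[str]) -> list[str]:
        out = []
        for ch in channel_labels:
            for a, b in self.bands_hz:
                out.append(f"bp{a:g}-{b:g}_{ch}")
            for tf in TIME_FEATURES:
                out.append(f"{tf}_{ch}")
        return out

    def to_dict(self) -> dict:
        return {"bands_hz": [list(b) for b in self.bands_hz], "log_epsilon": self.log_epsilon}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(tuple(tuple(b) for b in d["bands_hz"]), d.get("log_epsilon", 1e-12))


@dataclass
class FeatureMatrix:
    """Frame-by-feature matrix with warm-up mask and column names."""

    values: np.ndarray  # (n_frames, n_features_total), NaN on warm-up rows
    names: list[str]
    warmup: np.ndarray  # bool per frame
    frame_s: float = FRAME_S

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def valid(self) -> np.ndarray:
        return ~self.warmup

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "warmup", self.warmup.astype(int))
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        warm = df.pop("warmup").to_numpy().astype(bool)
        return cls(df.to_numpy(), list(df.columns), warm)


def band_power_features(
    window: np.ndarray, rate_hz: float, bands, eps: float
) -> np.ndarray:
    """Log mean Hann periodogram power per band, one row per channel."""
    window = np.atleast_2d(window)
    n = window.shape[1]
    freqs, psd = _sig.periodogram(window, fs=rate_hz, window="hann", detrend=False, axis=1)
    out = np.empty((window.shape[0], len(bands)))
    for j, (a, b) in enumerate(bands):
        if b >= rate_hz / 2:
            raise TremorLoopError(f"band ({a}, {b}) above Nyquist", code="band-out-of-range")
        sel = (freqs >= a) & (freqs <= b)
        if not np.any(sel):
            raise TremorLoopError(f"band ({a}, {b}) has no bins at n={n}", code="band-out-of-range")
        out[:, j] = np.log(eps + psd[:, sel].mean(axis=1))
    return out


def band_power_integrated(window: np.ndarray, rate_hz: float, band) -> np.ndarray:
    """Linear band power per channel: one-sided Hann PSD integrated over band.

    For a sinusoid of amplitude ``a`` inside the band this is ≈ ``a²/2``;
    for white noise it is the variance times the band's share of the
    Nyquist range.
    """
    window = np.atleast_2d(window)
    freqs, psd = _sig.periodogram(window, fs=rate_hz, window="hann", detrend=False, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise TremorLoopError(f"band {band} has no bins", code="band-out-of-range")
    df = freqs[1] - freqs[0]
    return psd[:, sel].sum(axis=1) * df


def time_domain_features(window: np.ndarray) -> np.ndarray:
    """RMS, line length, Hjorth mobility/complexity per channel."""
    window = np.atleast_2d(window)
    rms = np.sqrt(np.mean(window**2, axis=1))
    d1 = np.diff(window, axis=1)
    line = np.mean(np.abs(d1), axis=1)
    v0 = np.var(window, axis=1)
    v1 = np.var(d1, axis=1)
    d2 = np.diff(d1, axis=1)
    v2 = np.var(d2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(np.where(v0 > 0, v1 / np.where(v0 > 0, v0, 1.0), 0.0))
        mob_d = np.sqrt(np.where(v1 > 0, v2 / np.where(v1 > 0, v1, 1.0), 0.0))
        comp = np.where(mob > 0, mob_d / np.where(mob > 0, mob, 1.0), 0.0)
    return np.column_stack([rms, line, mob, comp])


def frame_features(window: np.ndarray, rate_hz: float, spec: FeatureSpec) -> np.ndarray:
    """The 12-per-channel feature vector of one frame, channels concatenated."""
    bp = band_power_features(window, rate_hz, spec.bands_hz, spec.log_epsilon)
    td = time_domain_features(window)
    return np.concatenate([np.concatenate([bp[c], td[c]]) for c in range(bp.shape[0])])


def extract_features(frames: FrameView, spec: FeatureSpec | None = None) -> FeatureMatrix:
    """Feature matrix over all frames of a framed signal; warm-up rows are NaN."""
    spec = spec or FeatureSpec()
    rate = frames.series.rate_hz
    for a, b in spec.bands_hz:
        if b >= rate / 2:
            raise TremorLoopError(f"band ({a}, {b}) above Nyquist", code="band-out-of-range")
    n_cols = spec.n_features * frames.series.n_channels
    values = np.full((frames.n_frames, n_cols), np.nan)
    for k in range(frames.n_frames):
        if frames.warmup[k]:
            continue
        values[k] = frame_features(frames.window(k), rate, spec)
    return FeatureMatrix(values, spec.names(frames.series.channel_labels), frames.warmup.copy())


@dataclass
class Normalizer:
    """Per-column standardization statistics learned on training frames."""

    mean: np.ndarray
    sd: np.ndarray  # floored, never zero

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]))


def fit_normalizer(
    features: FeatureMatrix, mask: np.ndarray | None = None, eps: float = 1e-12
) -> Normalizer:
    """Column mean/SD from the selected non-warm-up frames (SD floored)."""
    sel = features.valid()
    if mask is not None:
        sel = sel & np.asarray(mask, bool)
    rows = features.values[sel]
    if rows.shape[0] == 0:
        raise TremorLoopError("no frames to fit normalizer on", code="no-frames")
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd = np.where(sd < eps, eps, sd)
    return Normalizer(mean, sd)
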