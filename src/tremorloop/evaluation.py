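"""Offline evaluation: confusion rates, tremor power, energy, latency.

All metrics live on the 100 ms frame grid.  "Truth" is whatever indicates
when stimulation was actually needed: accelerometer/EMG-derived labels for
real-style sessions, or the generator's ground-truth motor states for
synthetic ones.  Rates are percentages of frames; TPR + FNR = 100 by
construction.  Delivered energy is an index proportional to
amplitude² × pulse charge-time × on-time — impedance is constant and
cancels in the A-DBS/C-DBS ratios that are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .core import FRAME_S, FrameSeries, TimeSeries, TremorLoopError
from .control import ClosedLoopTrace
from .labeling import tremor_band_power
from .synth import StimParams


@dataclass
class MetricsReport:
    """Everything the offline evaluation of one run produces."""

    accuracy: float
    tpr: float
    fpr: float
    fnr: float
    fn_episode_durations_s: list = field(default_factory=list)
    tremor_power: dict = field(default_factory=dict)  # condition -> mean band power
    suppression_pct: dict = field(default_factory=dict)  # condition -> %
    energy_index: dict = field(default_factory=dict)  # condition -> index
    energy_ratio_pct: float | None = None  # adbs / cdbs * 100

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "fn_episode_durations_s": list(map(float, self.fn_episode_durations_s)),
            "mean_fn_episode_s": (
                float(np.mean(self.fn_episode_durations_s))
                if len(self.fn_episode_durations_s)
                else None
            ),
            "tremor_power": self.tremor_power,
            "suppression_pct": self.suppression_pct,
            "energy_index": self.energy_index,
            "energy_ratio_pct": self.energy_ratio_pct,
        }


def confusion_metrics(
    detection: np.ndarray, truth: np.ndarray, valid: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """(accuracy, TPR, FPR, FNR) as percentages of frames.

    ``detection`` is the binary stimulation/detection trace, ``truth`` the
    binary needed-stimulation trace; ``valid`` excludes warm-up frames.
    """
    det = np.asarray(detection).astype(bool)
    tru = np.asarray(truth).astype(bool)
    if det.shape != tru.shape:
        raise TremorLoopError("detection/truth length mismatch", code="grid-mismatch")
    if valid is not None:
        det, tru = det[np.asarray(valid, bool)], tru[np.asarray(valid, bool)]
    n = len(tru)
    if n == 0:
        raise TremorLoopError("no frames", code="no-frames")
    n_pos = int(tru.sum())
    n_neg = n - n_pos
    if n_pos == 0:
        raise TremorLoopError("no positive truth frames", code="no-positives")
    accuracy = 100.0 * float(np.mean(det == tru))
    tpr = 100.0 * float(det[tru].sum()) / n_pos
    fpr = 100.0 * float(det[~tru].sum()) / n_neg if n_neg else 0.0
    fnr = 100.0 - tpr
    return accuracy, tpr, fpr, fnr


def fn_episodes(
    detection: np.ndarray, truth: np.ndarray, frame_s: float = FRAME_S
) -> list[float]:
    """Durations (s) of maximal runs where truth = 1 but detection = 0."""
    miss = np.asarray(truth).astype(bool) & ~np.asarray(detection).astype(bool)
    out = []
    run = 0
    for m in np.append(miss, False):
        if m:
            run += 1
        elif run:
            out.append(run * frame_s)
            run = 0
    return out


def tremor_power(
    accel: TimeSeries, frames_of_interest: np.ndarray | None = None, window_s: float = 0.5
) -> float:
    """Mean 3–7 Hz accelerometer band power over the selected frames."""
    power, warmup = tremor_band_power(accel, window_s)
    sel = ~warmup
    if frames_of_interest is not None:
        foi = np.asarray(frames_of_interest, bool)
        sel = sel & foi[: len(sel)]
    if not np.any(sel):
        raise TremorLoopError("no frames selected", code="no-frames")
    return float(np.mean(power[sel]))


def trace_tremor_power(trace: ClosedLoopTrace, frames_of_interest: np.ndarray) -> float:
    sel = ~trace.warmup & np.asarray(frames_of_interest, bool)
    if not np.any(sel):
        raise TremorLoopError("no frames selected", code="no-frames")
    return float(np.mean(trace.tremor_power[sel]))


def energy_index(trace: ClosedLoopTrace, stim: StimParams) -> float:
    """Delivered-energy index: Σ on-frames · V² · f · 2·pulse_width · Δt."""
    on_time = float(np.sum(trace.stim_on)) * trace.frame_s
    per_second = stim.amplitude_v**2 * stim.freq_hz * (2.0 * stim.pulse_us * 1e-6)
    return on_time * per_second


def suppression_pct(p_cond: float, p_nodbs: float) -> float:
    """Percent tremor-power reduction relative to the no-DBS condition."""
    if p_nodbs == 0:
        raise TremorLoopError("no-DBS tremor power is zero", code="undefined-suppression")
    return 100.0 * (p_nodbs - p_cond) / p_nodbs


def evaluate_trace(
    trace: ClosedLoopTrace,
    stim: StimParams,
    truth: np.ndarray | None = None,
    task_states=(1, 2),
) -> MetricsReport:
    """Confusion metrics + FN episodes for one closed-loop run.

    ``truth`` defaults to the trace's ground-truth motor states (any state
    in ``task_states`` counts as needing stimulation).
    """
    if truth is None:
        truth = np.isin(trace.truth_state, task_states)
    valid = ~trace.warmup
    acc, tpr, fpr, fnr = confusion_metrics(trace.stim_on, truth, valid)
    eps = fn_episodes(trace.stim_on[valid], np.asarray(truth, bool)[valid], trace.frame_s)
    return MetricsReport(acc, tpr, fpr, fnr, fn_episode_durations_s=eps)


def evaluate_conditions(
    traces: dict, stim: StimParams, frames_of_interest: np.ndarray | None = None
) -> MetricsReport:
    """Compare no-DBS / A-DBS / C-DBS runs of the same seeded session.

    ``traces`` maps condition names (``nodbs``, ``adbs``, ``cdbs``) to
    :class:`ClosedLoopTrace`; tremor power is averaged over
    ``frames_of_interest`` (default: ground-truth task frames).
    """
    if "nodbs" not in traces:
        raise TremorLoopError("need a nodbs reference trace", code="no-frames")
    ref = traces["nodbs"]
    foi = (
        np.isin(ref.truth_state, (1, 2))
        if frames_of_interest is None
        else np.asarray(frames_of_interest, bool)
    )
    report = evaluate_trace(traces.get("adbs", ref), stim)
    p_nodbs = trace_tremor_power(ref, foi)
    for cond, tr in traces.items():
        report.tremor_power[cond] = trace_tremor_power(tr, foi)
        report.energy_index[cond] = energy_index(tr, stim)
        if cond != "nodbs":
            report.suppression_pct[cond] = suppression_pct(report.tremor_power[cond], p_nodbs)
    if "adbs" in traces and "cdbs" in traces and report.energy_index["cdbs"] > 0:
        report.energy_ratio_pct = 100.0 * report.energy_index["adbs"] / report.energy_index["cdbs"]
    return report


def matched_tpr_threshold(
    scores: np.ndarray, truth: np.ndarray, matched_tpr: float
) -> float:
    """Score threshold whose TPR is closest to ``matched_tpr`` (ties → lower).

    Candidate thresholds are the observed positive-frame scores; raises
    ``tpr-unreachable`` if no threshold reaches the requested TPR.
    """
    truth = np.asarray(truth, bool)
    pos = np.sort(np.unique(scores[truth]))
    if len(pos) == 0:
        raise TremorLoopError("no positive frames", code="no-positives")
    cands = np.concatenate([pos, [np.nextafter(pos[-1], np.inf)]])
    tprs = np.array([(scores[truth] >= c).mean() for c in cands])
    if tprs.max() < matched_tpr - 1e-12:
        raise TremorLoopError("requested TPR unreachable", code="tpr-unreachable")
    err = np.abs(tprs - matched_tpr)
    best = err.min()
    # ties broken toward the lower threshold
    return float(cands[np.flatnonzero(np.isclose(err, best))[0]])


def trigger_latencies(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float,
    frame_s: float = FRAME_S,
    min_frames: int = 1,
) -> list[float]:
    """Per-trial latency (s) from truth onset to the DBS trigger.

    A trial is a maximal truth-positive run.  With ``min_frames = 1`` the
    trigger is the first above-threshold frame; larger values require a
    sustained run (e.g. 3 frames = 300 ms) and report its first frame, so
    a single noisy score spike does not count as a switch-on.  Trials that
    never trigger are skipped.
    """
    truth = np.asarray(truth, bool)
    det = np.asarray(scores) >= threshold
    out = []
    edges = np.flatnonzero(np.diff(truth.astype(int)))
    starts = [int(e) + 1 for e in edges if truth[e + 1]]
    if truth[0]:
        starts = [0] + starts
    ends = [int(e) + 1 for e in edges if not truth[e + 1]] + [len(truth)]
    for s in starts:
        e = next(x for x in ends if x > s)
        run = 0
        for i in range(s, e):
            run = run + 1 if det[i] else 0
            if run >= min_frames:
                out.append(float(i - min_frames + 1 - s) * frame_s)
                break
    return out


def anticipation_latency(
    movement_scores: np.ndarray,
    tremor_scores: np.ndarray,
    truth: np.ndarray,
    matched_tpr: float = 0.8,
    frame_s: float = FRAME_S,
    tremor_truth: np.ndarray | None = None,
    min_frames: int = 3,
) -> dict:
    """Mean DBS-trigger latency of a movement decoder vs a tremor decoder.

    Both decoders are evaluated on the same session.  Each gets the score
    threshold whose true-positive rate best matches ``matched_tpr``
    against its *own* positive class: task frames (``truth``) for the
    movement decoder, tremor frames (``tremor_truth``, e.g. accelerometer
    tremor labels; defaults to ``truth``) for the tremor decoder — tremor
    occupies only part of each task trial, so matching both decoders
    against task frames would force the tremor decoder out of its
    operating regime.  Latency is measured per trial from movement onset
    to the first sustained (``min_frames`` × 100 ms) detection.  Movement
    decoding is expected to anticipate tremor (smaller latency) because
    LFP movement signatures precede tremor development.
    """
    truth = np.asarray(truth, bool)
    if int(np.sum(np.diff(truth.astype(int)) == 1) + truth[0]) < 3:
        raise TremorLoopError("need >= 3 onsets", code="no-positives")
    match_truth = {
        "movement": truth,
        "tremor": truth if tremor_truth is None else np.asarray(tremor_truth, bool),
    }
    out = {}
    for name, scores in (("movement", movement_scores), ("tremor", tremor_scores)):
        scores = np.asarray(scores)
        thr = matched_tpr_threshold(scores, match_truth[name], matched_tpr)
        lats = trigger_latencies(scores, truth, thr, frame_s, min_frames)
        out[name] = {
            "threshold": thr,
            "latencies_s": lats,
            "mean_latency_s": float(np.mean(lats)) if lats else np.nan,
        }
    out["latency_difference_s"] = (
        out["movement"]["mean_latency_s"] - out["tremor"]["mean_latency_s"]
    )
    return out


def paired_compare(values_a, values_b) -> tuple[float, float]:
    """Paired t-test on per-session values; returns (t, p).

    Identical vectors give (0, 1); constant nonzero differences (zero
    variance, infinite t) raise ``degenerate-pairs``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or len(a) < 2:
        raise TremorLoopError("need equal-length vectors, n >= 2", code="degenerate-pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise TremorLoopError("zero variance of differences", code="degenerate-pairs")
    res = _stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
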