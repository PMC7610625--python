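# Methods

`tremorloop` simulates and evaluates a responsive ("closed-loop") deep-brain
stimulation system for essential tremor.  The system decodes
tremor-provoking motor states — self-paced voluntary movement or sustained
posture — from thalamic (VIM/ZI) local field potentials recorded on the
stimulation electrodes themselves, and gates a 130 Hz stimulator on and off
at a 10 Hz update rate.  Because no patient recordings of this kind are
publicly deposited, the package pairs the decoding/control stack with a
synthetic-session generator carrying ground truth, so every stage is
testable end to end.

## The control problem

Essential tremor is intermittent: it appears during voluntary movement and
sustained posture and is absent at rest.  Continuous VIM stimulation
(C-DBS) therefore delivers current when none is needed.  The adaptive
controller (A-DBS) solves a per-frame binary decision problem: every 100 ms,
given the trailing window of bipolar LFP, decide whether a tremor-provoking
state is present; if so the stimulator is on at its clinically effective
amplitude, otherwise at 0 V.  The controller is a pure function of the
current detection — no debounce, no ramping — and because stimulation
changes the recorded signal (artifact and neural effects), two classifiers
per task are kept and the one matching the stimulator state during the
scored window (the state set at the previous frame) is used.

## Signal chain

1. **Band-pass** 0.5–500 Hz, forward-only 8th-order Butterworth in
   second-order sections.  Real-time operation forbids zero-phase
   filtering; streaming state is carried so chunked and whole-signal
   filtering agree exactly.  "8th order" is read as the overall band-pass
   order (a 4th-order low-pass prototype).
2. **Framing**: frame *k* is the half-open interval [k·0.1 s, (k+1)·0.1 s).
   At 2048 Hz a frame holds 204 or 205 samples; boundaries are defined once
   as `round(k·204.8)` and shared by every module.  Each frame exposes the
   trailing 500 ms analysis window ending at its right edge.  The window
   length is a config knob, not a constant: 500 ms resolves the 3–7 Hz
   tremor band at 2 Hz bin spacing while keeping latency acceptable.
   Frames before one full window are warm-up: no features, no detection.
3. **Features** (12 per bipolar channel, channels concatenated): log mean
   Hann-periodogram power in eight bands — 3–7, 8–12, 13–20, 21–30, 31–45,
   55–95, 105–195, 205–395 Hz — plus RMS, line length, Hjorth mobility and
   complexity on the same window.  The bands cover the reported effects
   (theta up with posture, beta down and gamma up with movement) while
   avoiding 50 Hz mains; the two high bands carry stimulation-artifact
   energy, which is informative for the stim-on decoders.  The exact
   twelve features used online are not public, so the set is configurable.
4. **Labels** are never taken from the LFP: movement labels come from the
   2-means split of the log EMG total-activity envelope (high-pass 10 Hz,
   rectified, per-frame RMS), tremor labels from the 2-means split of log
   3–7 Hz accelerometer band power.  The 1-D 2-means is exact (sorted
   prefix-sum search, no random starts).  A flip requires three consecutive
   frames (300 ms hysteresis).  A unimodal envelope yields all-zero labels;
   unimodality is declared when cluster separation is under 1 % of the
   range or under 3× the mean within-cluster spread — a plain range
   criterion alone never fires on log-scale noise.
5. **Classifiers**: SVM (linear, C=1), logistic regression, LDA, Gaussian
   naive Bayes, decision tree, k-NN, and a two-layer random-projection
   extreme learning machine, all behind one score-in-[0,1] interface.
   Cross-validation is 5-fold by protocol block, never by frame —
   neighbouring frames share most of their window, so frame-wise folds
   leak.  The best cross-validated AUC per (task × stim-state) cell is
   retrained on all of that cell's data.  AUC is the trapezoidal integral
   of the pooled out-of-fold ROC; tests verify it equals pair-counting to
   1e−9.
6. **Tremor intensity**: an SVR (RBF, C=10, ε=0.01) maps the same features
   to log tremor-band accelerometer power on stimulation-off frames;
   predictions are exponentiated and clipped at zero.

## Synthetic sessions

The generator is streaming: every 100 ms frame is produced from carried
filter and RNG state, so open-loop generation and closed-loop simulation
(where the controller chooses each frame's stimulation state) are the same
process.  Identical seeds give byte-identical sessions.

* **LFP** = 1/f background (IIR pink-noise approximation, 5 µV RMS) plus
  band-limited noise oscillations (band-passed white noise, so spectra show
  bands rather than lines): beta 2 µV at rest, halved during
  movement/posture; theta 1 µV, doubled during posture; gamma 0.5 µV,
  doubled during movement.  Envelope changes are smoothed with a 200 ms
  one-pole so state edges are not clicks.
* **Tremor** is a 5 Hz oscillation whose amplitude obeys a first-order
  relaxation toward a state-dependent target: 0 at rest; 0.3 g after 5 s of
  sustained task (the onset delay follows the one patient for whom the
  paper shows the time course); rise τ = 5 s, release τ = 1 s once the limb
  rests, and τ = 2 s toward (1 − 0.53) of the unstimulated level while
  stimulation is on.  The 0.53 steady-state suppression echoes the
  continuous-DBS group mean.  The asymmetry (slow regrowth, fast
  suppression) is what lets brief false-negative stimulation gaps pass
  without tremor re-emerging, as observed online.
* **Tremor in the LFP**: an 8 µV tremor-frequency component scaled by the
  instantaneous tremor amplitude.  Thalamic tremor-band oscillations during
  overt tremor are the dominant low-frequency LFP feature (tremor cells);
  this component is what makes tremor decodable and tremor intensity
  predictable from LFP alone.  At small values the posture-related theta
  increase (same band) masks it and a "tremor decoder" degenerates into a
  posture decoder.
* **Accelerometer**: tremor projected on a fixed random axis plus 20 mg
  white sensor noise; movement blocks add 0.5–20 Hz band noise (0.3 g) so
  accelerometer-based movement labeling sees both low-frequency motion and
  >10 Hz content.
* **EMG**: white noise whose envelope rises 5× during task (200 ms
  smoothing), amplitude-modulated at the tremor frequency when tremor is
  present.
* **Stimulation artifact**: the 130 Hz biphasic pulse train (60 µs phases,
  20 µs gap) is synthesized on a 25× fine grid, shaped by a 2nd-order
  150 Hz low-pass standing for the electrode–tissue/front-end coupling,
  and decimated to 2048 Hz *without* anti-alias filtering, so pulse
  harmonics above the 1024 Hz Nyquist frequency fold back to
  |k·130 − round(k·130/2048)·2048| Hz.  The shaping is what makes the
  fundamental the dominant line, as in real recordings; an unshaped
  rectangular train has harmonic amplitudes growing with frequency and its
  aliased images would dominate the spectrum instead.  Artifact amplitude
  relative to LFP is nowhere quantified; the default (5 µV RMS, equal to
  the background) makes the artifact the dominant PSD line while leaving
  stim-on decoding in the reported AUC range — at 10× background, stim-on
  decoding collapses to chance, which contradicts the study's results.
  Artifact is gated to stimulation-on frames (off frames are bit-identical
  to the artifact-free signal) and is purely additive; amplifier
  saturation is out of scope.
* **Patient vs session randomness**: per-channel artifact coupling and
  oscillation gains are electrode properties, drawn from `patient_seed`
  and constant across sessions; all noise realizations follow the session
  `seed`.  Decoders are trained and applied within one subject, as in the
  study.

What the generator does **not** emulate: non-stationary drift, stun-effect
decay over days, movement artifacts in the LFP, imperfect charge balance or
amplifier nonlinearity, EEG, and inter-patient anatomy.  Passing tests show
the pipeline is correct and that the loop behaves as reported *under these
idealized conditions*; they do not show that decoding accuracy would
transfer to any real recording.

## Evaluation

All metrics live on the frame grid, warm-up excluded.  Accuracy, TPR, FPR,
FNR are percentages of frames (TPR + FNR = 100 exactly); false-negative
episodes are maximal runs of missed task frames; tremor power is the
integrated 3–7 Hz accelerometer band power averaged over task frames;
delivered energy is the index Σ on-frames · V² · f · (2·pulse width) · Δt,
defined up to the constant tissue impedance, which cancels in the
A-DBS/C-DBS ratio; suppression is the percent reduction versus the no-DBS
run of the same seeded session.  Paired session-level comparisons use the
paired t-test (identical vectors report t = 0, p = 1; constant non-zero
differences are rejected as degenerate rather than reported as infinite).

For the movement-versus-tremor anticipation comparison, each decoder's
threshold is set so its true-positive rate matches the requested level
against its *own* positive class — task frames for the movement decoder,
accelerometer-derived tremor frames for the tremor decoder.  Tremor
occupies only ~70 % of task time under the 5 s onset delay, so matching
both against task frames would force the tremor decoder below its
operating regime.  The trigger time within a trial is the first frame of
the first 300 ms sustained detection (same 3-frame constant as the
labeling hysteresis); a single noisy frame above threshold is not a
meaningful switch-on.  The strict first-frame definition remains available
(`trigger_latencies(min_frames=1)`).

## Numerical and design choices

* Table I/O writes floats with 17 significant digits and reads them with
  the round-trip parser: lossless for finite doubles.  EDF export
  quantizes to 16 bits over a symmetric per-channel range with 1 %
  headroom; the error bound is half a step.  EDF needs whole-second
  durations (1 s records).
* Algorithm ties in model selection break in the fixed order
  svm > lr > lda > nb > dt > knn > helm.
* Matched-TPR threshold ties break toward the lower threshold.
* Degenerate inputs raise typed errors with machine-readable codes
  (`degenerate-labels`, `too-few-blocks`, `schedule-mismatch`,
  `no-positives`, …) rather than returning NaNs.
* Problem sizes used in tests and examples — 3 LFP channels, 15–30 s
  blocks, 3–6 blocks per session, 5 seeds for the closed-loop comparison —
  are chosen so the whole suite runs in minutes on one core while leaving
  every per-seed property comfortably clear of its threshold.

## Known limitations

* The four-model grid assumes the stimulator state is known exactly; there
  is no modeling of telemetry loss or state desynchronization.
* The binary controller cannot titrate amplitude; the tremor-intensity SVR
  exists for that extension but no proportional controller is provided.
* The one-frame model-selection lag is the only loop delay; within-frame
  computation time is idealized to zero.
* HELM's architecture is a plausible small ELM, not a reference
  implementation of any published variant.
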