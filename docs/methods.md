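# Methods

This note documents the models, default parameters and numerical choices
behind `eogkit`, and what the synthetic experiments do and do not show.

## Signal model

The electrooculogram is treated as linear in gaze angle.  For each
channel (horizontal H, vertical V) the electrode-pair voltage changes by
`s` µV per degree of eye rotation; a saccade therefore appears as a step
whose height encodes the movement size and whose sign encodes its
direction.  The package's sign convention is rightward = positive H,
upward = positive V.  The inverse map, `angle = k · EOG_variation`, is
the linear saccadic model; `k` (degrees per signal unit) is a per-user,
per-channel constant fitted during calibration.  Fixations between
saccades are nominally constant but carry drift, mains pickup and
wide-band noise; blinks superimpose a short positive pulse on V only.

## Synthetic generator: what it emulates

Defaults were chosen once as the study conditions for all experiments
and tests:

| parameter | default | rationale |
| --- | --- | --- |
| sensitivity `uv_per_degree` | 15 µV/deg | places 10–40° saccades (150–600 µV) inside the physiological EOG range of 50–3,500 µV |
| saccade transition | 40 ms logistic | ballistic saccades complete in 30–50 ms |
| blink pulse | 300 µV, 250 ms, 30 ms rise | eyelid artefacts are large, fast-rising, and over well before a held fixation ends |
| drift | 20 µV RMS, white noise low-passed at 0.1 Hz | slow electrode/skin baseline wander |
| mains | 5 µV at 50 Hz, random phase | residual interference after the analogue front end |
| white noise | 5 µV SD | amplifier and muscle noise |
| front end | ×20 differential stage; ×0–250 second stage (256 pot steps, default 100); 0.05–35 Hz first-order band-pass; 12-bit ADC over 3.3 V at 100 Hz | mirrors a two-stage AC-coupled biopotential amplifier; total per-channel gain 0–5,000 |

The band-pass is applied causally (cascaded first-order digital
filters), as the analogue hardware would; its group delay at saccade
frequencies is well under one sample at 100 Hz, so ground-truth indices
are the scheduled onsets.  The 0.05 Hz high-pass gives AC coupling: a
held deflection decays with a ~3.2 s time constant.  Because the
amplitude-change measurement (below) reads flanking windows within
±150 ms of the transition, the resulting droop is a few percent and is
identical in calibration and detection, so it cancels out of the angle
estimate.

What the generator does **not** model: electrode-impedance changes, skin
contact artefacts, head/facial motion, overshoot and ripple of real
saccades, gaze jitter during fixation, and spontaneous (non-scripted)
blinks with variable waveforms.  Passing tests on synthetic data
therefore demonstrate the correctness and internal consistency of the
pipeline under the stated noise model — not human-subject performance.
In particular, the simulated protocol's success rates are not claims
about real users; the five-user reference table in
`evaluation.FIVE_USER_BENCHMARK` is reproduced only as arithmetic.

## Single-scale CWT

The Haar/db1 mother wavelet (+1 on [0, ½), −1 on [½, 1)) is dilated to
scale `a = 60` samples, sampled at the integer grid points of its
support, L2-normalized by `1/√a`, and de-meaned (a no-op for even
integer scales; for odd or fractional scales it restores exact zero
response to constants).  The transform is a correlation with this single
kernel.  Closed forms used as oracles: constants map to 0; a rising unit
step yields a triangular response with extremum `−√a/2` at the step
sample (the sign convention is fixed by the +/− order of the Haar
wavelet; detection uses the magnitude, and the movement's sign is read
from the amplitude change, not from the coefficient).

Two alignments are provided.  `center` places each coefficient at the
middle of the wavelet support (extremum lands on the step sample) and is
used for calibration and analysis.  `causal` places the support entirely
in the past (coefficient `j` uses samples ≤ `j`; group delay
`a − 1 − a//2` = 29 samples at `a = 60`) and is used by the detection
pipeline so that its outputs never depend on samples beyond the declared
lookahead.  Boundaries are handled by symmetric padding (start-only for
the causal alignment).

## Calibration and quantification

Each calibration segment contains one saccade of known signed angle.
The CWT peak locates the transition; the EOG variation is the
difference between the medians of 100 ms windows placed 50 ms after and
before it (medians resist impulsive noise; the gap skips the transition
itself).  The gain is the least-squares slope of angle on variation
constrained through the origin — the model has no intercept, and an
unconstrained intercept would absorb drift.  The detection threshold
defaults to 0.5 × the smallest calibration peak: halfway between the
smallest movement that must be detected and the noise floor, which the
CWT's magnification keeps far below it.  The candidate refractory period
is 200 ms, applied greedily in time order (an accepted detection is
never retracted by a later larger peak — the causal, online rule).

## RBF validator and the ELM solve

The network is `f(x) = Σᵢ βᵢ exp(−‖wᵢ∘x − μᵢ‖²/σᵢ²)` with 20 hidden
units over 50-sample CWT windows `[t−25, t+24]`.  The per-neuron input
weights are applied elementwise before centre subtraction, following the
basis-function form adopted here; a conventional `‖x − μᵢ‖` mode is
available behind a flag and behaves equivalently in practice.  Random
scheme: `wᵢ ~ U(−1,1)` per element; `μᵢ` uniform over the per-feature
span of the (scaled) training data; `σᵢ ~ U(0.5, 2)·√d` in scaled
feature space.  The `√d` factor keeps 50-dimensional squared distances
commensurate with `σ²`; without it every activation underflows toward
zero and the solve degenerates.  `β` is the minimum-norm least-squares
solution `H⁺T` (LAPACK `gelsd` via `numpy.linalg.lstsq`), verified in
tests against an explicit pseudoinverse oracle at 1e-8.

Two numerical choices matter:

* **Global input scale.**  Features are divided by the training
  windows' global standard deviation (stored in the model) so the
  random-parameter ranges are data-independent.
* **Per-window L2 normalization** (default).  Each window is scaled to
  a common L2 norm before entering the network, so the validator judges
  the *shape* of the coefficient window — step-like transition versus
  blink/fixation/rest — rather than its amplitude.  Amplitude screening
  is the threshold stage's job.  Without this, a network trained on the
  four discrete calibration amplitudes rejects saccades of intermediate
  size (scores 0.2–0.5 for 11–16° movements); with it, recall on held-out
  amplitudes is complete.  Near-silent windows are floored so rest stays
  near the origin rather than being blown up to unit norm.

Training data are assembled from the calibration recording itself: one
positive window per true saccade on its moving channel, augmented with
±2-sample jitter; negatives are blink-pulse windows and event-free
stretches of both channels, to a default total of one hundred 50-sample
segments at roughly balanced classes.  The decision threshold is 0.5,
midway between the 0/1 regression targets.

## Blink template and clicks

The template is the pointwise mean of onset-aligned blink segments,
linearly resampled to a fixed length and z-scored.  Matching is sliding
Pearson correlation: scale- and offset-invariant, and sign-sensitive
(an inverted waveform cannot match).  Local maxima above the similarity
threshold (default 0.8), kept non-overlapping in time order, become
blink events.  Two refinements proved necessary and are on by default in
the pipeline (both off at the module level, where the primitive is pure
correlation):

* **Amplitude criterion.**  Correlation is blind to scale, so smooth
  drift segments correlate highly with the pulse shape (~23 false
  blinks/min under the default drift; ~0 under white noise).  The
  pipeline's template therefore also requires a matched window to reach
  0.4 × the median calibration-blink peak-to-peak amplitude.
* **Baseline-padded segments.**  Pipeline templates span 100 ms of
  pre-onset baseline + pulse + return-to-baseline tail (450 ms total,
  45 samples) instead of the bare 300 ms pulse.  A blink is over within
  the window while a saccadic step persists — with bare-pulse templates
  the plateau-then-fall of a downward vertical saccade matched at
  r ≈ 0.81–0.83 and the resulting false blinks discarded the saccade
  via coincidence.  With padded templates those matches vanish.

Clicks are greedy left-to-right groups of exactly 2 (or 3) consecutive
blinks whose onset span fits the configured interval (default 2 s);
groups never share blinks, so clicks are disjoint.

## Fusion, commands and the real-time contract

A candidate survives iff the network accepts its window and no blink
onset lies within ±250 ms of it; discarded candidates are not
re-detected.  Surviving H and V candidates within 50 ms merge into one
oblique movement (the channel-merge window is shorter than the
refractory period, so merges are unambiguous).  Direction classes are
45° sectors centred on the 8 directions; movements below 5° on both
axes carry no class and are dropped.  Command decoding scans events in
time order: a validated saccade opens (or supersedes) the pending
selection; the first click starting within the 2 s validation window
after it emits the mapped command and closes the selection.

The detection phase is causal by construction: CWT in causal alignment,
greedy refractory and non-overlapping rules, and windows that only reach
`lookahead` (25 samples = 250 ms) past the detection point.  A validated
saccade with onset `t` is emitted at
`t + max(causal_delay + lookahead, coincidence + template_len)` samples
(70 samples = 700 ms with defaults — the blink-arbitration window, which
must close before a coincident blink can be ruled out, is the binding
term).  The truncation test verifies this: altering samples after an
event's emission sample never changes it.

## Sizes used by the standard experiments

* Angle accuracy (`angle_accuracy_experiment`): one calibration session
  (4 angles × 2 channels, out and back, 3 double blinks) and one
  200-saccade test series, 10–40° uniform, default noise; mean absolute
  error over matched detections (matching tolerance ±250 ms).  Typical
  result ≈ 0.7° MAE at full recall, against the 2° working bound.
* Detection precision/recall (`detection_metrics`): 20 independent
  sessions of 10 saccades plus single- and double-blink distractors,
  each with its own calibration; aggregate precision and recall both
  ≥ 0.95 under default noise.
* Protocol simulation (`run_protocol`): per selection, a 5 s slot with
  select-saccade (20°), double blink at +0.8 s, return at +2.7 s; every
  selection graded exactly once, failures attributed to selection vs
  validation.  An optional tiredness ramp scales noise and drift with
  test index; it is qualitative only.

## Known limitations

* The linear gain `k` is fitted once; real EOG sensitivity wanders with
  electrode conditions, and no online recalibration is provided.
* Smooth pursuit, vergence and gaze jitter are neither modelled nor
  classified; everything below the CWT threshold is invisible.
* The blink detector assumes voluntary blinks resemble the calibration
  blinks; waveform variability across blink types is not modelled.
* At 100 Hz a 40 ms saccade transition spans ~4 samples, so transition
  shape is barely resolved; the amplitude-change estimator is designed
  around this (flanking medians, not slope fitting).
* The 50 Hz mains term sits at the Nyquist frequency of the default
  100 Hz rate and aliases to an alternating-sign sequence; it stands in
  for residual interference rather than reproducing true mains pickup.
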