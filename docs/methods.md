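# Methods

## Signal model and decomposition

An insertion is a sequence of time points; at each one the recording system
delivers an averaged rarefaction waveform and an averaged condensation
waveform (100 presentations each), 12 ms at 20 kHz, in microvolts.  The
cochlear microphonic follows the stimulus and inverts with its polarity,
while the neurophonic is a rectification-like distortion that does not, so

    DIF = (r − c) / 2        SUM = (r + c) / 2

separate the two.  The halving is a deliberate convention: a pure CM of
amplitude A yields a DIF of amplitude exactly A, which keeps the 1 µV
inclusion threshold and all plotted amplitudes on the physical scale.

Amplitude and phase are read from one bin of the DFT after zero-padding the
240-sample window to 1000 samples (bin spacing 20 Hz).  The amplitude scale
is 2·|X[k]|/240 — the *unpadded* length — so a full-window unit cosine
measures 1.0.  Frequencies must lie on a bin; the API rejects others rather
than silently interpolating.  Phase is the principal value in (−π, π];
downstream features use sin(phase), so the branch cut is immaterial.

CM is measured from DIF at {500, 1000, 1500, 2000} Hz and ANN from SUM at
the paired 2nd harmonics {1000, 2000, 3000, 4000} Hz.  Only the fundamental
pair (500/1000) feeds the primary features; the others enter the optional
96-value extended set.

**Inclusion rule.**  A recording is usable only if its band-limited DIF
reaches 1 µV — the level needed to clear the recording system's noise floor
with enough margin to see a 30% drop.  The band filter is an order-15 FIR
(Hamming design, passband 0.9F–1.1F) applied forward-backward for zero
phase; a window's amplitude is half its filtered peak-to-trough range.  An
FIR was chosen because an odd "order-15 bandpass" is unambiguous for FIR
where IIR bandpass order conventions are not, and the zero-phase application
avoids latency distortion of the reading.

## Peak tracking

Drops are judged against the most recent *meaningful* maximum of the CM
amplitude trace, not against every wiggle.  The tracker confirms a local
peak at t−1 when amp[t−2] < amp[t−1] ≥ amp[t] (mirrored for troughs, so a
plateau ending in a fall registers its first point), pairs each peak with
the most recent prior trough (the stream's first sample before any trough
exists), and promotes a peak to **active peak** when (a) none exists, (b) it
exceeds the standing active peak, or (c) it exceeds s_a = 0.5 of the
standing active peak *and* its prominence over the paired trough exceeds
s_b = 0.1 of the peak.  The tracker is strictly causal with one-sample
latency (an event at i is known when i+1 arrives) and never rewrites
history; a consequence is that at the very time point of a new peak the
feature set still references the previous active peak.

## Features and normalisation

Eight features per falling-edge time point (first valid index t = 4, since
the variability window needs five points):  baselined ‖CM‖ and ‖ANN‖
(per-channel mean of the first five readings subtracted, absorbing
between-patient response-size differences), sin of each phase, raw
‖CM‖/‖ANN‖, raw ‖CM‖/‖CM‖_pk, t_pk − t (non-positive by construction), and
the coefficient of variation std/mean of the raw ‖CM‖ over t−4…t with the
sample (n−1) standard deviation.  Ratios use raw amplitudes because
baselining can produce negatives.  Guards: a zero ANN amplitude maps the
ratio to a large sentinel (bounded later by clipping); before the first
active peak the peak ratio is 1 and the lag 0 (a neutral "at the peak"
state); a zero-mean variability window yields 0.  Features are min-max
scaled to [0, 1] with the *training* fold's extrema; test values are clipped
into [0, 1] so the classifier never sees out-of-domain inputs, and a
constant training feature maps to 0.

The extended mode concatenates the 8 features over all four harmonic pairs
and a three-point trailing window (96 values, valid from t = 6).

## Classification

The reference model is AdaBoost over depth-1 decision trees, 100 rounds,
learning rate 0.3, with 'drop' instances carrying a misclassification-cost
weight.  Two choices deserve explanation:

* **Stumps with shrinkage.**  With deeper trees at unit learning rate the
  boosted ensemble drives the weighted training loss to zero on a few
  thousand points, after which the cost weighting has no purchase on the
  decision boundary and the cost-response curve goes flat.  Shrunk stumps
  keep residual training loss alive, restoring the intended monotone
  trade-off — raising the cost buys sensitivity at the price of specificity —
  and generalise better to unseen patients.
* **Cost as class-weighted loss.**  The cost multiplies the boosting sample
  weights of drop instances.  An alternative — thresholding the ensemble's
  posterior at 1/(1+cost) at prediction time — was evaluated and rejected:
  boosted-ensemble posteriors concentrate near 0.5, so that rule saturates
  within the first grid steps and makes the search degenerate.

The search grid is integer costs 1–60 in steps of 2.  Each cost is scored by
patient-grouped 5-fold cross-validation (each fold holds ≥ 1 drop patient),
with post-processing and early-detection credit applied, and the winner
maximises min(sensitivity, specificity); ties break toward higher accuracy,
then lower cost.  The natural starting point for a single fixed cost is the
'no drop' : 'drop' class ratio.  Any binary classifier can be substituted
through the model descriptor (a k-nearest-neighbour variant is built in);
feature importance is the ensemble's normalised impurity-decrease weight,
averaged across fold models and renormalised.

## Post-processing and evaluation

Two causal rules run in one forward pass, Rule 1 before Rule 2 at each
point:  (1) a falling point whose predecessor on the *same* contiguous
falling run is a (corrected) 'drop' is also a 'drop'; (2) a falling 'drop'
whose 5-point amplitude window has sample std below s_c = 0.01 times the
window minimum is vetoed to 'no drop'.  Evaluating Rule 2 second means
propagation cannot carry a drop across a flat stretch.  At t < 4 the window
shrinks to the available points (minimum two; the veto is skipped at t = 0).
The pass is idempotent.

Metrics are computed over classified points only (falling edges with a valid
feature vector):  sensitivity TD/(TD+FND), specificity TND/(TND+FD),
accuracy (TD+TND)/all.  A predicted drop that precedes an expert interval on
the same falling run — no intervening local peak — is an *early detection*
and is counted as a true drop rather than a false one; this credit can only
shrink the false-drop count.  Cross-validation reports the unweighted mean
of per-fold metrics (pooled-count metrics are exposed as a secondary view).
Undefined metrics (zero denominator) are reported as NaN, never silently as
0 or 1.

## Synthetic cohorts

The generator emulates what the pipeline consumes, with exact ground truth:

* **CM trajectory**: per-patient baseline uniform in 1–30 µV, multiplied by
  a log-amplitude random walk with step sd 0.02 (≈ 2% per time point, a
  realistic slow fluctuation as the electrode advances; resampled in the
  rare case a spurious ≥ 30% decline appears, so injected drops are the only
  drops).  100 time points per insertion, 40 patients by default.
* **Drops**: a fixed-size random subset of patients (⌈n·drop_prob⌉, default
  30%) receives one drop: a strictly geometric decline of depth uniform in
  30–60% over 3–8 points, after which the walk resumes at the reduced level —
  trauma does not heal mid-insertion.  The annotation runs from one point
  after onset (a 1-point expert reaction delay) to the nadir; the ground
  truth interval covers every strictly falling point.
* **Waveforms**: CM and ANN (ANN = 0.2 × CM) are rendered as full-window
  cosines with per-patient random phases, CM components sign-flipping with
  polarity and ANN components not; harmonic content decays by 0.15 per
  step so all four measurement pairs carry signal.  Every frequency used
  completes an integer number of cycles in the window and sits on a DFT bin,
  so at zero noise the readout is mathematically exact — this is what makes
  the 1e−9 round-trip checks possible.  ANN is a pure 2F tone rather than a
  biophysical half-wave-rectified response: the pipeline only reads the 2F
  bin, so nothing more is observable.
* **Noise**: white Gaussian, sd 0.1 µV per averaged waveform, standing in
  for residual noise after 100-presentation averaging.

What the generator does *not* emulate — and hence what green tests do not
establish about clinical data: real intra-operative noise is neither white
nor stationary (electrocautery bursts, movement artifacts); real drops are
not cleanly geometric and may partially recover; real CM phase drifts with
insertion depth; expert labels carry human timing variability far richer
than a fixed 1-point delay; and inter-patient variability has structure
(audiogram, anatomy) beyond a baseline scale factor.  Synthetic performance
figures are an internal-consistency result, not a clinical claim.

## Numerical and interface choices

* Time points are 0-based; annotation intervals are closed on both ends.
* Recording files store samples with 17 significant digits (bit-exact round
  trips); the reader uses round-trip float parsing.
* Problem sizes in the test suite and the reproduction script follow the
  default cohort (40 patients × 100 time points, ≈ 2000 falling-edge
  instances, 30-point cost grid), which a single CPU handles in about a
  minute.
* All randomness flows through explicit integer seeds: cohort generation,
  fold assignment and ensemble training are each deterministic given theirs.

## Known limitations

* The post-processing pass and the evaluation's falling-run scan are O(n)
  per point in the streaming detector (quadratic per insertion); at
  clinical insertion lengths (hundreds of points) this is negligible.
* Rule 1 interprets "previous point on a falling edge" as the immediately
  preceding point of the same falling run; drops therefore never propagate
  across an intervening rise, and Rule 2 may veto a propagated label.  Other
  readings of the rule order are defensible; this one prevents flat-region
  false positives from spreading.
* The misclassification-cost search assumes sensitivity/specificity vary
  smoothly enough over the grid that a step of 2 suffices; a finer schedule
  costs proportionally more cross-validation runs.
* With very small cohorts (< 5 drop patients) the grouped 5-fold constraint
  is infeasible by design; use fewer folds.
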