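# Methods

## Problem and scope

`exertsense` implements an end-to-end method for recognizing physical
exertions (power grips) in occupational tasks from a wrist/forearm armband
that records 8 channels of surface EMG (sEMG, microvolts) and a 6-DOF IMU
(3-axis accelerometer in g, 3-axis gyroscope in degrees per second), sampled
at 500 Hz. The chain is: unit calibration of raw sensor counts -> an ordered
noise-treatment sequence -> MVC-based normalization of the sEMG ->
sliding-window time-domain features -> a quadratic-kernel SVM that labels
each window *exertion* (1) or *non-relevant* (2) -> a two-factor factorial
experiment that selects which optional treatments to apply. Exertion
detection of this kind is the first input to ergonomic risk scores for
work-related musculoskeletal disorders; the score computation itself is out
of scope.

## Signal chain

Fixed constants (units in parentheses) and their roles:

| stage | constant | value |
|---|---|---|
| LSB calibration | sEMG / gyro / acc | 0.045 uV, 0.015267 dps, 0.061035e-3 g per count |
| sEMG band-pass | Butterworth order, band | 4, 30-120 Hz |
| gyro low-pass | Butterworth order, cutoff | 4, 7 Hz |
| Hampel identifier | window, threshold | 1001 samples, 3 sigma (MAD x 1.4826) |
| RMS envelope | window | 25 samples |
| MVC RMS maximum | half-window | 250 samples (501-sample segment) |
| zero calibration | reference block | first 500 samples (1 s of rest) |
| feature windows | size, overlap | 125 samples, 50 % (step 63) |
| classifier | kernel, C, CV | poly degree 2 (coef0 = 1, gamma = "scale"), C = 1, stratified 5-fold |
| factorial design | factors, levels, replicates, alpha | E x F, 2 x 2, 3, 0.05 |

Treatment codes: **A** Hampel outlier replacement (rectified sEMG and
inertial channels), **B** per-sample labeling from the beep/boop event
marks, **C** merging of per-recording feature tables, **D** sliding-window
feature extraction, **E** offset removal on the *normalized* sEMG envelope
(subtract the channel minimum), **F** zero calibration of inertial channels
(subtract the mean of the first 500 rest samples). A, B, C, D are always
applied; E and F are the experimental factors. The selected chain applies
them in the order E, F, A, B, C, D. The "worst" baseline used for contrast
is Butterworth filtering plus direct normalization of the rectified sEMG
(no A, no envelope smoothing, no E/F).

Numerical choices the sources of the constants leave open:

- **Phase handling.** All filtering is zero-phase (forward-backward,
  `sosfiltfilt`), so burst onsets stay aligned with the event marks used
  for labeling; the effective magnitude response is the squared one-pass
  Butterworth response, which the tests check against the analytic form.
- **Hampel edges and ties.** Windows are centered and truncated at the
  series edges; the MAD is scaled by 1.4826 to estimate sigma; a zero-MAD
  window falls back to an absolute threshold floor of 1e-9 of the signal
  scale so constant segments are not mass-replaced. The kernel (a numba
  sorted-buffer implementation, O(N x W) worst case) is tested for exact
  equality against a brute-force per-window oracle.
- **Envelope and window alignment.** The RMS envelope uses centered
  truncated windows and preserves length. Feature windows start at
  0, 63, 126, ... while they fit entirely; 50 % of a 125-sample window is
  fractional, so the step is 125 - floor(62.5) = 63.
- **Window label rule.** Majority of the per-sample labels; an exact tie
  goes to *exertion*, biasing toward recall, which is the conservative
  direction for a safety application.
- **Zero-variance kurtosis.** The non-excess kurtosis of a constant window
  is undefined; it is set to 0 so the feature table stays dense. Std/var
  use the sample (n-1) denominator; kurtosis uses the biased moment
  estimator (a normal window gives ~3).
- **E inside the ordering.** The design-table orderings list E before
  normalization in time, yet E is defined on the *normalized* signal; the
  only self-consistent reading, implemented here, applies E immediately
  after normalization within the sEMG sub-chain whenever E is enabled.
- **Accelerometer filtering.** Only the gyroscope's 7 Hz low-pass is
  specified; the accelerometer is left unfiltered by default with a
  `filter_acc` switch.
- **Replacement rule.** The per-channel normalization denominator is the
  larger of the MVC and the task windowed-RMS maxima; when the task wins,
  the normalized windowed RMS is bounded by 1 by construction (tested).

## Synthetic data model

No public recordings ship with the package; the generator (`synth`)
produces sessions with exact ground truth so every stage is testable. What
it emulates, and why:

- **sEMG bursts**: Gaussian noise band-limited to 20-150 Hz (where real
  surface EMG carries most of its power), amplitude-modulated by a
  raised-cosine activation envelope (~0.2 s ramps). Burst amplitude is the
  per-subject RMS at full activation (drawn 150-450 uV across subjects);
  each grip gets a random intensity in [0.5, 1]. Signals are generated
  post-notch: the device removes line interference before recording, so
  none is present by default (an optional 50/60 Hz term exists for filter
  tests).
- **Rest baseline**: mean rectified amplitude 1-3.5 uV (the accepted QC
  band for a clean recording), plus sub-15 uV random spikes during
  inactivity.
- **Electrode-muscle matching**: per-channel gains in [0.4, 1] fixed per
  armband placement (shared between a subject's MVC and task recordings),
  with a per-run "posture wobble" of [0.8, 1.25] because a task posture
  never loads the muscles exactly like the calibration grip — MVC
  normalization is deliberately imperfect, as it is in practice.
- **MVC session**: one sustained maximal burst (gain 1.3-1.8 over the task
  amplitude) with 5 s rest padding on both sides.
- **Non-relevant activity (class 2)**: the task between grips is not
  quiescence. Brief movements (0.3-1.5 s, ~1.5 per gap) activate the same
  muscles with a random-to-near-uniform channel pattern and carry their own
  IMU transients and orientation excursions. This continuum up to
  "grip-like handling" is what makes the classification problem non-trivial
  — without it, any window statistic separates the classes perfectly and
  treatment effects are invisible.
- **IMU model**: the accelerometer reads the gravity projection of a slowly
  wandering forearm orientation; during grips the orientation is pulled to
  a stereotyped grip posture (a fixed ~0.4 g delta from the wearer's
  neutral, small per-run jitter). Background arm activity is present in
  both classes and the per-grip motion intensity overlaps its range, so
  *posture*, not motion level, is the class-informative inertial cue —
  which is exactly the cue sensor bias corrupts and zero calibration
  restores. Transients (~0.3 s damped oscillations) occur at grip edges and
  at non-relevant movements alike.
- **Corruptions** (mild by default; the `SynthConfig.corrupted()` preset is
  uniformly severe): large artifact spikes (per-sample rate 5e-3, up to
  ~3000 uV) that the Hampel stage removes; residual muscle tone — a
  per-recording constant activation of the task muscles (up to ~60 % of a
  weak grip after normalization) that appears as the offset of the
  normalized envelope and is what treatment E removes; accelerometer /
  gyroscope biases (up to ~0.9 g / 90 dps per axis) that zero calibration
  removes; and slow drift (~8e-3 g/s, 0.8 dps/s) that nothing in the chain
  removes and that therefore bounds all conditions. Bias factors are drawn
  positive so that increasing the configured offset strictly increases the
  pre-calibration baseline mean (a tested invariant).

What the generator does **not** model: motor-unit action potentials or
force-EMG dynamics, electrode lift-off, posture-dependent muscle
recruitment changes within a grip, cross-talk between channels, and
device-specific packet loss. Passing tests therefore show that the chain
recovers the structure this model encodes — levels, floors, biases,
spikes, posture — not that it reaches any particular accuracy on real
recordings.

## Reference study and problem sizes

The package's end-to-end study runs at desk scale, chosen for single-CPU
runtimes while keeping every preprocessing constant at its full value:

- **Selected chain, clean conditions**: cohorts of 9 subjects (8 train,
  1 held out) x 2 runs, 6 grips of ~2 s separated by ~2 s gaps with 5 s
  lead-in/out; three independent cohort draws. Held-out accuracy,
  precision, recall and F1 all land near the mid-to-high 90s (%).
- **Baseline chain, corrupted conditions**: a 15-subject x 2-run cohort
  under the severe preset with ~1.5 s grips/gaps (shorter runs buy more
  recordings at equal cost). The last three subjects are evaluated
  leave-one-subject-out with pooled confusion counts, because a single
  held-out wearer makes the estimate hinge on one corruption draw.
  Pooled accuracy typically falls in the mid-to-high 80s — about 8-15
  points below the selected chain depending on the cohort draw.
- **Factorial experiment**: the corrupted cohort's 14 training subjects;
  4 cells x 3 replicates, where a replicate re-seeds the cross-validation
  folds over the same merged table (the only stochastic element of the
  trained response; what varied across the original replicates is not
  recorded). Cell means are ~0.94 (neither), ~0.95 (E), ~0.96 (F), ~0.96+
  (both); both main effects are significant far below the 0.05 level, and
  the optimizer returns (E applied, F applied).

A deliberate property of this design: with only ~10-30 recordings, a
quadratic SVM evaluated by row-level cross-validation can partially
*memorize* per-recording constants (a bias or tone level acts as a
recording-identity context), which suppresses — and can even invert — the
apparent benefit of harmonizing treatments. The corrupted study therefore
uses more, shorter recordings and corruption severe enough that recordings
collide in feature space; at the original study's scale (56 training
datasets) this memorization pressure is far smaller.

## Known limitations

- Cohort-to-cohort variance of the held-out scores is a few points; the
  worst-chain score in particular depends on which corruption levels the
  held-out subjects draw. The reference seeds fix one realization; the
  acceptance script recomputes everything for any seed.
- The classifier's hyperparameters are fixed to the classic "quadratic SVM"
  preset (degree-2 polynomial, C = 1, standardized features); no search is
  performed, by design.
- Per-window evaluation is implemented (matching the confusion-matrix
  framing); `windows_to_intervals` exists for interval-level rendering but
  no interval-level metric is defined.
- The factorial replicates share the processed data within a cell; they
  quantify fold-assignment noise only, so the ANOVA's error term is an
  optimistic lower bound on true replication error.
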