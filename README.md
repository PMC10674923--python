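# exertsense

Physical-exertion recognition from a wearable armband that records
8-channel surface EMG (sEMG) and a 6-DOF inertial unit at 500 Hz, for
occupational-ergonomics studies of repetitive manual work (the eventual
consumers are ergonomic risk scores such as the Job Strain Index, whose
"intensity/duration of exertion" inputs require knowing *when* a worker is
exerting force).

The package implements the full method:

1. **I/O and calibration** — read/write the armband CSV dialect, convert
   raw counts to physical units (sEMG 0.045 uV, gyro 0.015267 dps,
   acc 0.061035e-3 g per count), decode beep/boop event marks (1/2) into
   ground-truth exertion intervals.
2. **Noise-treatment chain** — 4th-order zero-phase Butterworth filters
   (30–120 Hz band-pass for sEMG, 7 Hz low-pass for the gyroscope),
   rectification, Hampel outlier identification (window 1001, 3 sigma),
   25-sample RMS envelopes, MVC normalization (per-channel division by the
   RMS maximum of a maximal-effort calibration recording, with the
   task-replacement rule), offset removal (**E**) and zero calibration
   (**F**).
3. **Features** — 125-sample windows with 50 % overlap; 9 time-domain
   statistics (mean, min, max, std, var, median, range, RMS, kurtosis) per
   signal x 14 signals = 126 features per window, plus the majority class
   label (1 exertion / 2 non-relevant).
4. **Classification** — a quadratic-kernel SVM
   (`ExertionQSVM.fit() -> ExertionQSVMResults`) with standardized
   features and stratified 5-fold cross-validation; confusion-matrix
   metrics with exertion as the positive class.
5. **Treatment selection** — a 2x2x3 factorial experiment over E and F
   (`TreatmentFactorial.fit() -> FactorialResults`): two-way ANOVA with
   interaction at alpha = 0.05 and a response optimizer that picks the
   accuracy-maximizing cell with a pooled-error confidence interval.
6. **Synthetic sessions** — a generator for MVC + task recordings with
   exact ground truth and controllable corruption (artifact spikes,
   residual muscle tone, IMU bias and drift), so the whole chain is
   testable without any device data. See `docs/methods.md` for the model
   and its limits.

## Worked example

```python
import exertsense as ex

# one synthetic subject: calibration + task session with ground truth
cfg = ex.SynthConfig(seed=7)
task, truth = ex.generate_task(cfg)
mvc = ex.generate_mvc(cfg)

# selected treatment ordering: E, F, A, B, C, D
processed = ex.apply_treatments(task, mvc, "EFABCD")
table = ex.build_feature_table(processed)
print(table.shape)

results = ex.ExertionQSVM(table).fit(folds=5, seed=0)
print(results.summary())

report = results.evaluate(table)
print(report.summary())
```

prints

```
(271, 130)
Quadratic-kernel SVM exertion detector
  training rows        271
  features             126
  CV folds (stratified) 5, seed 0
  CV training accuracy 95.94 %
  fold accuracies      96.36, 94.44, 92.59, 100.00, 96.30
confusion matrix (positive = exertion):
  TP=92  FN=3
  FP=0  TN=176
accuracy   98.89 %
precision 100.00 %
recall     96.84 %
F1 score   98.40 %
```

The table has 271 windows and 130 columns: the 126 features plus label,
window start, subject and run. The cross-validated training accuracy
(95.94 %) is the quantity the factorial experiment optimizes; the
confusion matrix here is on the training windows themselves (held-out
evaluation goes through `exertsense.holdout_metrics`, which trains on all
but one subject of a cohort).

A command-line layer wraps the same functions:

```sh
exertsense simulate --seed 7 --out session/
exertsense featurize --task session/task.csv --mvc session/mvc.csv \
    --treatments EFABCD --out features.csv
exertsense train --features features.csv --seed 0 --out model.joblib
exertsense evaluate --model model.joblib --features features.csv
exertsense doe --subjects 8 --replicates 3 --report doe.json
```

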