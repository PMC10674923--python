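"""The noise-treatment chain and its QC diagnostics.

Stages, in the order the selected pipeline applies them to a task recording:

- sEMG: 4th-order 30-120 Hz band-pass Butterworth (zero-phase) -> full-wave
  rectification -> Hampel identifier (window 1001, 3 sigma) -> 25-sample RMS
  envelope -> division by the per-channel MVC RMS maximum (with the
  task-replacement rule) -> optional offset removal (treatment E, subtract
  the channel minimum of the *normalized* envelope);
- gyroscope: 4th-order 7 Hz low-pass (zero-phase); accelerometer unfiltered
  by default (configurable);
- inertial: optional zero calibration (treatment F, subtract the mean of the
  first 500 rest samples), then Hampel (treatment A);
- labels (treatment B) attached per sample from the beep/boop marks.

Treatment codes follow the factorial design table: A Hampel, B labeling,
C merging, D feature windowing (C and D live in :mod:`exertsense.features`),
E offset removal on normalized sEMG, F zero calibration of inertial data.
The "worst" baseline chain (Butterworth filtering plus direct normalization
of the rectified sEMG, no A/E/F and no envelope smoothing) is provided for
the treatment-contrast experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._hampel import _hampel_core
from .io import RawRecording, pair_marks

EMG_BANDPASS_HZ = (30.0, 120.0)
GYRO_LOWPASS_HZ = 7.0
FILTER_ORDER = 4
HAMPEL_WINDOW = 1001
HAMPEL_N_SIGMA = 3.0
RMS_WINDOW = 25
MVC_HALF_WINDOW = 250          # +/-250 samples around the envelope maximum
ZERO_CAL_N_REF = 500
BASELINE_N = 500

#: Valid treatment orderings (design table rows) plus the baseline contrast.
ORDERINGS: dict[str, list[str]] = {
    "ABCD": ["A", "B", "C", "D"],
    "EABCD": ["E", "A", "B", "C", "D"],
    "FABCD": ["F", "A", "B", "C", "D"],
    "EFABCD": ["E", "F", "A", "B", "C", "D"],
    "worst": ["B", "C", "D"],
}


@dataclass
class FilterSpec:
    """Butterworth design: kind ('bandpass'|'lowpass'), order, cutoff(s) in Hz."""

    kind: str
    order: int
    cutoffs: tuple[float, ...] | float

    def __post_init__(self):
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"kind must be 'bandpass' or 'lowpass', got {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        cuts = self.cutoffs if isinstance(self.cutoffs, (tuple, list)) else (self.cutoffs,)
        self.cutoffs = tuple(float(c) for c in cuts)
        if self.kind == "bandpass" and len(self.cutoffs) != 2:
            raise ValueError("bandpass needs (low, high) cutoffs")
        if self.kind == "lowpass" and len(self.cutoffs) != 1:
            raise ValueError("lowpass needs a single cutoff")


EMG_FILTER = FilterSpec("bandpass", FILTER_ORDER, EMG_BANDPASS_HZ)
GYRO_FILTER = FilterSpec("lowpass", FILTER_ORDER, GYRO_LOWPASS_HZ)


@dataclass
class MVCProfile:
    """Per-channel normalization denominators (uV) and their source.

    ``source[c]`` is "MVC" when the calibration recording supplied the
    denominator and "task_replaced" when the task's own RMS maximum exceeded
    it and replaced it.
    """

    rms_max: np.ndarray
    source: list[str]

    def __post_init__(self):
        self.rms_max = np.asarray(self.rms_max, dtype=float)
        if np.any(self.rms_max <= 0):
            raise ValueError("all MVC denominators must be > 0 (flat channel?)")


@dataclass
class ProcessedRecording:
    """Treatment-chain output: normalized sEMG envelopes, calibrated inertial
    channels, per-sample labels, and the ordered treatment log."""

    emg_norm: np.ndarray          # (8, N), dimensionless, >= 0
    acc_cal: np.ndarray           # (3, N), g
    gyro_cal: np.ndarray          # (3, N), dps
    fs: float
    labels: np.ndarray            # (N,), {1, 2}
    treatment_log: list[str]
    subject_id: str = ""
    run: int = 1
    mvc_profile: MVCProfile | None = None
    hampel_outliers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.emg_norm.shape[1]

    @property
    def signals(self) -> dict[str, np.ndarray]:
        """All 14 named signal series, in feature-table column order."""
        out = {f"ch{i + 1}": self.emg_norm[i] for i in range(self.emg_norm.shape[0])}
        for i, name in enumerate(("accX", "accY", "accZ")):
            out[name] = self.acc_cal[i]
        for i, name in enumerate(("gyroX", "gyroY", "gyroZ")):
            out[name] = self.gyro_cal[i]
        return out


def butterworth(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filter, length-preserving.

    Zero-phase filtering keeps burst onsets aligned with the event marks used
    for labeling; its magnitude response is the squared one-pass response.
    """
    series = np.asarray(series, dtype=float)
    nyq = fs / 2
    if any(not (0 < c < nyq) for c in spec.cutoffs):
        raise ValueError(f"cutoffs {spec.cutoffs} must lie within (0, {nyq}) Hz")
    sos = sps.butter(spec.order, spec.cutoffs if spec.kind == "bandpass" else spec.cutoffs[0],
                     btype=spec.kind, fs=fs, output="sos")
    # sosfiltfilt needs padlen < n; require a sane margin
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.size <= max(3 * spec.order, padlen):
        raise ValueError(f"series of length {series.size} too short for order-{spec.order} filtering")
    return sps.sosfiltfilt(sos, series)


def rectify(series: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(series, dtype=float))


def hampel(series: np.ndarray, window: int = HAMPEL_WINDOW,
           n_sigma: float = HAMPEL_N_SIGMA) -> tuple[np.ndarray, np.ndarray]:
    """Hampel identifier with centered, edge-truncated windows.

    Returns the cleaned series and the indices of replaced samples. Samples
    deviating from the rolling median by more than ``n_sigma`` scaled-MAD
    units are replaced by that median; zero-MAD windows fall back to an
    absolute floor of 1e-9 of the signal scale.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("hampel expects a 1-D series")
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    floor = 1e-9 * (scale if scale > 0 else 1.0)
    out, flagged = _hampel_core(x, (window - 1) // 2, float(n_sigma), floor)
    return out, np.flatnonzero(flagged)


def rms_envelope(series: np.ndarray, window: int = RMS_WINDOW) -> np.ndarray:
    """Centered moving RMS, length-preserving with truncated edge windows."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(f"series length {x.size} shorter than window {window}")
    half = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x ** 2)))
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(x.size, idx + (window - half))
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def mvc_rms_max(envelope_channel: np.ndarray, half_window: int = MVC_HALF_WINDOW) -> float:
    """RMS of the (2*half_window + 1)-sample segment centered at the global
    maximum of an envelope channel, truncated at the boundaries."""
    x = np.asarray(envelope_channel, dtype=float)
    if x.size < 2 * half_window + 1:
        raise ValueError(
            f"channel length {x.size} < {2 * half_window + 1}; recording too short for calibration")
    peak = int(np.argmax(x))
    seg = x[max(0, peak - half_window): peak + half_window + 1]
    return float(np.sqrt(np.mean(seg ** 2)))


def build_mvc_profile(mvc_envelopes: np.ndarray, task_envelopes: np.ndarray) -> MVCProfile:
    """Per-channel denominators: the MVC RMS maximum, replaced by the task's
    own RMS maximum whenever the task exceeds the calibration."""
    mvc_envelopes = np.asarray(mvc_envelopes, dtype=float)
    task_envelopes = np.asarray(task_envelopes, dtype=float)
    if mvc_envelopes.shape[0] != task_envelopes.shape[0]:
        raise ValueError("MVC and task envelope sets must have the same channel count")
    denominators = []
    source = []
    for c in range(mvc_envelopes.shape[0]):
        mvc_val = mvc_rms_max(mvc_envelopes[c])
        task_val = mvc_rms_max(task_envelopes[c])
        if task_val > mvc_val:
            denominators.append(task_val)
            source.append("task_replaced")
        else:
            denominators.append(mvc_val)
            source.append("MVC")
    return MVCProfile(rms_max=np.array(denominators), source=source)


def normalize_emg(task_envelopes: np.ndarray, profile: MVCProfile) -> np.ndarray:
    """Divide each task envelope channel by its MVC denominator."""
    task_envelopes = np.asarray(task_envelopes, dtype=float)
    if task_envelopes.shape[0] != profile.rms_max.size:
        raise ValueError(
            f"channel-count mismatch: {task_envelopes.shape[0]} envelopes vs "
            f"{profile.rms_max.size} denominators")
    return task_envelopes / profile.rms_max[:, None]


def remove_offset(series: np.ndarray) -> np.ndarray:
    """Treatment E: set the baseline at the lowest data point (subtract min)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove offset of an empty series")
    return x - x.min()


def zero_calibrate(series: np.ndarray, n_ref: int = ZERO_CAL_N_REF) -> np.ndarray:
    """Treatment F: subtract the mean of the first ``n_ref`` (rest) samples."""
    x = np.asarray(series, dtype=float)
    if x.size <= n_ref:
        raise ValueError(f"series length {x.size} must exceed n_ref={n_ref}")
    return x - x[:n_ref].mean()


def _emg_envelopes(rec: RawRecording, use_hampel: bool,
                   outliers: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Band-pass -> rectify -> (Hampel) -> RMS envelope for all 8 channels."""
    env = np.empty_like(rec.emg)
    for c in range(rec.emg.shape[0]):
        x = rectify(butterworth(rec.emg[c], EMG_FILTER, rec.fs))
        if use_hampel:
            x, idx = hampel(x)
            if outliers is not None:
                outliers[f"ch{c + 1}"] = idx
        env[c] = rms_envelope(x)
    return env


def _rectified_emg(rec: RawRecording) -> np.ndarray:
    out = np.empty_like(rec.emg)
    for c in range(rec.emg.shape[0]):
        out[c] = rectify(butterworth(rec.emg[c], EMG_FILTER, rec.fs))
    return out


def apply_treatments(task: RawRecording, mvc: RawRecording, ordering: str = "EFABCD",
                     filter_acc: bool = False) -> ProcessedRecording:
    """Run the treatment chain named by ``ordering`` on a task recording.

    ``ordering`` is a design-table row ("ABCD", "EABCD", "FABCD", "EFABCD")
    or "worst" (Butterworth filtering + direct normalization only). The MVC
    recording supplies the normalization denominators; ``filter_acc`` extends
    the 7 Hz low-pass to the accelerometer (off by default).
    """
    if ordering not in ORDERINGS:
        raise ValueError(f"unknown ordering {ordering!r}; choose from {sorted(ORDERINGS)}")
    apply_e = "E" in ORDERINGS[ordering] and ordering != "worst"
    apply_f = "F" in ORDERINGS[ordering]
    apply_a = "A" in ORDERINGS[ordering]
    outliers: dict[str, np.ndarray] = {}

    if ordering == "worst":
        # baseline contrast: filtered + rectified sEMG normalized directly
        task_rect = _rectified_emg(task)
        mvc_rect = _rectified_emg(mvc)
        profile = build_mvc_profile(mvc_rect, task_rect)
        emg_norm = normalize_emg(task_rect, profile)
    else:
        task_env = _emg_envelopes(task, use_hampel=apply_a, outliers=outliers)
        mvc_env = _emg_envelopes(mvc, use_hampel=apply_a)
        profile = build_mvc_profile(mvc_env, task_env)
        emg_norm = normalize_emg(task_env, profile)
        if apply_e:
            emg_norm = np.vstack([remove_offset(ch) for ch in emg_norm])

    gyro = np.vstack([butterworth(g, GYRO_FILTER, task.fs) for g in task.gyro])
    acc = (np.vstack([butterworth(a, GYRO_FILTER, task.fs) for a in task.acc])
           if filter_acc else task.acc.copy())
    if apply_f:
        acc = np.vstack([zero_calibrate(a) for a in acc])
        gyro = np.vstack([zero_calibrate(g) for g in gyro])
    if apply_a:
        cleaned_acc, cleaned_gyro = [], []
        for i, a in enumerate(acc):
            y, idx = hampel(a)
            outliers[("accX", "accY", "accZ")[i]] = idx
            cleaned_acc.append(y)
        for i, g in enumerate(gyro):
            y, idx = hampel(g)
            outliers[("gyroX", "gyroY", "gyroZ")[i]] = idx
            cleaned_gyro.append(y)
        acc, gyro = np.vstack(cleaned_acc), np.vstack(cleaned_gyro)

    labels = pair_marks(task.marks, task.n_samples).labels(task.n_samples)
    return ProcessedRecording(
        emg_norm=emg_norm, acc_cal=acc, gyro_cal=gyro, fs=task.fs, labels=labels,
        treatment_log=list(ORDERINGS[ordering]), subject_id=task.subject_id,
        run=task.run, mvc_profile=profile, hampel_outliers=outliers,
    )


def estimate_baseline_noise(series: np.ndarray, intervals, n: int = BASELINE_N) -> float:
    """Mean rectified amplitude (uV) over an ``n``-sample rest window.

    Uses the central ``n`` samples of the first rest segment (outside all
    exertion intervals) long enough to qualify; clean recordings should fall
    in the 1-3.5 uV band.
    """
    x = np.asarray(series, dtype=float)
    rest = np.ones(x.size, dtype=bool)
    for start, end in intervals:
        rest[start:end] = False
    # enumerate maximal rest runs
    padded = np.concatenate(([0], rest.view(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= n:
            mid = (s + e) // 2
            lo = max(s, mid - n // 2)
            return float(np.mean(np.abs(x[lo:lo + n])))
    raise ValueError(f"no rest segment of >= {n} samples available")


def welch_psd(series: np.ndarray, n: int = 500, fs: float = 500.0,
              start: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of an ``n``-sample segment starting at ``start``."""
    x = np.asarray(series, dtype=float)
    if x.size < start + n:
        raise ValueError(f"series too short for a {n}-sample segment at {start}")
    freqs, psd = sps.welch(x[start:start + n], fs=fs, nperseg=n)
    return freqs, psd


def band_power_fraction(freqs: np.ndarray, psd: np.ndarray,
                        band: tuple[float, float]) -> float:
    """Fraction of total spectral power inside ``band`` (QC diagnostic)."""
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        return 0.0
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]) / total)
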