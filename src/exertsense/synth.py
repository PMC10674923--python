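"""Synthetic armband sessions with known ground truth.

Emulates MVC-calibration and task recordings as the device delivers them
*after* its on-board notch/DC filtering: exertion bursts are band-limited
(default 20-150 Hz) amplitude-modulated Gaussian noise; rest carries a 1-3.5 uV
baseline floor plus sub-15 uV random spikes; occasional large artifact spikes,
electrode-contact noise pedestals, IMU biases and slow drift provide the
controllable corruption that the treatment chain is meant to remove. Event
marks 1/2 bracket every true exertion, so mark pairing reproduces the ground
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import RawRecording, ExertionIntervals

_HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)  # E|x| = sigma * sqrt(2/pi) for Gaussian x
_MAX_DURATION_S = 600.0


@dataclass
class SynthConfig:
    """Generation parameters for one synthetic subject/session.

    Amplitude conventions: ``emg_burst_amp_uv`` is the RMS (i.e. the
    instantaneous envelope) of the band-limited burst noise at full
    activation; ``baseline_noise_uv`` is the *mean rectified* rest amplitude
    (the quantity baseline-noise QC estimates), kept in the 1-3.5 uV band of
    a clean recording. Corruption magnitudes default to mild, realistic
    levels; :meth:`corrupted` returns the heavy preset used for the
    worst-pipeline contrast and the factorial experiment.
    """

    seed: int = 0
    fs: float = 500.0
    n_grips: int = 6
    grip_duration_s: float = 2.0
    gap_duration_s: float = 2.0
    duration_jitter: float = 0.2          # fractional jitter on grip/gap lengths
    lead_in_s: float = 5.0
    lead_out_s: float = 5.0
    ramp_s: float = 0.2                   # raised-cosine on/off ramp

    emg_burst_amp_uv: float = 300.0
    grip_intensity_range: tuple[float, float] = (0.5, 1.0)  # per-grip peak multiplier
    # non-relevant activity (class 2): brief movements between grips, e.g.
    # repositioning the workpiece - partial muscle activation with a
    # different channel pattern, plus arm-movement IMU transients
    distractor_rate_per_gap: float = 1.5
    distractor_amp_range: tuple[float, float] = (0.3, 0.9)   # x subject burst amp
    distractor_duration_s: tuple[float, float] = (0.3, 1.5)
    emg_band: tuple[float, float] = (20.0, 150.0)
    channel_gain_range: tuple[float, float] = (0.4, 1.0)
    # electrode-muscle matching gains; fixed per armband placement, so MVC and
    # task recordings of one subject share them. None -> drawn from the seed.
    channel_gains: tuple[float, ...] | None = None
    # per-run wobble of the effective gains: the task posture loads muscles
    # slightly differently from the calibration grip; (1, 1) = perfect match
    task_gain_wobble: tuple[float, float] = (0.8, 1.25)
    baseline_noise_uv: float = 2.0
    rest_spike_amp_uv: float = 12.0       # < 15 uV, per QC guidance
    rest_spike_rate_hz: float = 1.0
    line_interference_uv: float = 0.0     # optional 50/60 Hz term for filter tests
    line_freq_hz: float = 60.0

    outlier_rate: float = 1e-4            # per-sample artifact-spike probability
    outlier_amp_uv: float = 1500.0
    # residual muscle tone: sustained low-level activation of the task
    # muscles (same channel pattern as the grips) when the subject does not
    # fully relax between exertions; a per-recording constant that appears as
    # the offset of the normalized envelope that treatment E removes
    emg_offset_uv: float = 0.0
    acc_offset_g: float = 0.02
    gyro_offset_dps: float = 1.0
    acc_drift_g_per_s: float = 1e-4
    gyro_drift_dps_per_s: float = 0.02

    acc_noise_g: float = 0.005
    gyro_noise_dps: float = 0.5
    acc_transient_g: float = 0.25
    gyro_transient_dps: float = 40.0
    acc_motion_g: float = 0.05            # low-frequency motion while the arm is active
    gyro_motion_dps: float = 10.0
    acc_wander_g: float = 0.12            # slow orientation wander outside grips

    mvc_gain: float = 1.5                 # MVC burst amplitude / task burst amplitude
    mvc_burst_s: float = 5.0

    def validate(self) -> None:
        if self.n_grips < 0:
            raise ValueError("n_grips must be >= 0")
        for name in ("grip_duration_s", "gap_duration_s", "lead_in_s", "lead_out_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        low, high = self.emg_band
        if not (0 < low < high < self.fs / 2):
            raise ValueError(f"emg_band {self.emg_band} must lie within (0, fs/2)")
        total = (self.lead_in_s + self.lead_out_s
                 + self.n_grips * (self.grip_duration_s + self.gap_duration_s) * (1 + self.duration_jitter))
        if total > _MAX_DURATION_S:
            raise ValueError(f"configured duration ~{total:.0f}s exceeds sanity cap {_MAX_DURATION_S}s")

    @classmethod
    def corrupted(cls, **overrides) -> "SynthConfig":
        """Heavy-corruption preset: contact-noise pedestal, large IMU biases,
        faster drift and more frequent high-amplitude artifact spikes."""
        base = dict(
            emg_offset_uv=320.0,
            acc_offset_g=0.6,
            gyro_offset_dps=60.0,
            acc_drift_g_per_s=8e-3,
            gyro_drift_dps_per_s=0.8,
            outlier_rate=5e-3,
            outlier_amp_uv=3000.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """True exertion intervals plus the per-sample class labels (1/2)."""

    intervals: ExertionIntervals
    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], rms: float) -> np.ndarray:
    """Band-limited Gaussian noise normalized to the requested RMS."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, white)
    denom = np.sqrt(np.mean(x ** 2))
    if denom == 0:
        return np.zeros(n)
    return x * (rms / denom)


def _transient(n: int, center: int, fs: float, rng: np.random.Generator,
               amp: float) -> np.ndarray:
    """Short-lived (~0.3 s) damped oscillation centered near a grip edge."""
    width = int(0.3 * fs)
    t = np.arange(-width // 2, width // 2) / fs
    f = rng.uniform(3.0, 6.0)
    pulse = amp * rng.uniform(0.6, 1.0) * np.exp(-(t / 0.08) ** 2) * np.cos(
        2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    out = np.zeros(n)
    lo = max(0, center - width // 2)
    hi = min(n, center + width // 2)
    out[lo:hi] = pulse[(lo - (center - width // 2)):(hi - (center - width // 2))]
    return out


def _grip_intervals(cfg: SynthConfig, rng: np.random.Generator) -> tuple[int, list[tuple[int, int]]]:
    fs = cfg.fs
    cursor = int(cfg.lead_in_s * fs)
    intervals = []
    for _ in range(cfg.n_grips):
        grip = cfg.grip_duration_s * (1 + cfg.duration_jitter * rng.uniform(-1, 1))
        gap = cfg.gap_duration_s * (1 + cfg.duration_jitter * rng.uniform(-1, 1))
        start = cursor
        end = start + max(int(grip * fs), int(0.5 * fs))
        intervals.append((start, end))
        cursor = end + max(int(gap * fs), int(0.5 * fs))
    n = cursor + int(cfg.lead_out_s * fs)
    return n, intervals


def _channel_gains(cfg: SynthConfig) -> np.ndarray:
    if cfg.channel_gains is not None:
        gains = np.asarray(cfg.channel_gains, dtype=float)
        if gains.shape != (8,):
            raise ValueError("channel_gains must have 8 entries")
        return gains
    gain_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
    return gain_rng.uniform(*cfg.channel_gain_range, size=8)


def _ramped_segment(length: int, ramp: int) -> np.ndarray:
    seg = np.ones(length)
    ramp = min(ramp, length // 2)
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        seg[:ramp] = up
        seg[length - ramp:] = up[::-1]
    return seg


def _distractor_events(cfg: SynthConfig, rng: np.random.Generator,
                       intervals: list[tuple[int, int]], n: int):
    """Non-relevant movements inside the gaps between grips: each event has a
    random per-channel activation pattern and an IMU motion scale."""
    events = []
    gaps = [(intervals[i][1], intervals[i + 1][0]) for i in range(len(intervals) - 1)]
    for lo, hi in gaps:
        for _ in range(rng.poisson(cfg.distractor_rate_per_gap)):
            dur = int(rng.uniform(*cfg.distractor_duration_s) * cfg.fs)
            if hi - lo <= dur + 2:
                continue
            start = int(rng.integers(lo, hi - dur))
            amp = rng.uniform(*cfg.distractor_amp_range)
            # channel pattern spans a continuum from a movement-specific
            # subset of muscles to near-grip co-activation (e.g. steadying
            # the workpiece engages the same muscles as the grip)
            unif = rng.uniform(0.0, 1.0)
            weights = unif + (1 - unif) * rng.uniform(0.0, 1.0, size=8) ** 1.5
            events.append({"span": (start, start + dur), "amp": amp,
                           "weights": weights, "imu": rng.uniform(0.5, 1.2)})
    return events


def _emg_channels(cfg: SynthConfig, rng: np.random.Generator, n: int,
                  activation_uv: np.ndarray, rest_mask: np.ndarray) -> np.ndarray:
    """Carrier band-noise amplitude-modulated by the (8, n) activation (uV)."""
    fs = cfg.fs
    sigma_rest = cfg.baseline_noise_uv / _HALF_NORMAL_MEAN
    emg = np.empty((8, n))
    for c in range(8):
        carrier = _band_noise(rng, n, fs, cfg.emg_band, 1.0)
        x = carrier * (sigma_rest + activation_uv[c])
        if cfg.line_interference_uv > 0:
            t = np.arange(n) / fs
            x = x + cfg.line_interference_uv * np.sin(2 * np.pi * cfg.line_freq_hz * t)
        # sub-15 uV random spikes in inactivity periods
        rest_idx = np.flatnonzero(rest_mask)
        n_spikes = rng.poisson(cfg.rest_spike_rate_hz * rest_idx.size / fs)
        if n_spikes > 0 and rest_idx.size:
            pos = rng.choice(rest_idx, size=n_spikes, replace=False)
            x[pos] += rng.uniform(3.0, cfg.rest_spike_amp_uv, size=n_spikes) * rng.choice((-1.0, 1.0), size=n_spikes)
        # occasional large artifact spikes anywhere
        out_mask = rng.random(n) < cfg.outlier_rate
        n_out = int(out_mask.sum())
        if n_out:
            x[out_mask] += (rng.uniform(0.5, 1.0, size=n_out) * cfg.outlier_amp_uv
                            * rng.choice((-1.0, 1.0), size=n_out))
        emg[c] = x
    return emg


# forearm orientation (gravity components, g) in the stereotyped grip posture,
# relative to the wearer's neutral rest posture
_GRIP_POSTURE_DELTA_G = np.array([0.30, 0.20, -0.18])


def _imu_channels(cfg: SynthConfig, rng: np.random.Generator, n: int,
                  env_grip: np.ndarray, edges: list[int],
                  events: list[dict] | None = None,
                  env_motion: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Accelerometer/gyroscope model.

    The accelerometer reads the gravity projection of a slowly wandering
    forearm orientation that is pulled to a common grip posture during
    exertions and to random excursions during non-relevant movements, plus
    sensor bias, drift, motion noise and grip-edge transients. The gyroscope
    carries continuous background rotation whose level overlaps the grip
    motion, so posture - not motion per se - is the class-informative cue.
    """
    fs = cfg.fs
    t = np.arange(n) / fs
    events = events or []
    acc = np.empty((3, n))
    gyro = np.empty((3, n))
    # positive per-axis bias factors keep the offset -> baseline-mean relation monotone
    acc_bias = cfg.acc_offset_g * rng.uniform(0.5, 1.5, size=3)
    gyro_bias = cfg.gyro_offset_dps * rng.uniform(0.5, 1.5, size=3)
    acc_drift = cfg.acc_drift_g_per_s * rng.uniform(0.5, 1.5, size=3) * rng.choice((-1.0, 1.0), size=3)
    gyro_drift = cfg.gyro_drift_dps_per_s * rng.uniform(0.5, 1.5, size=3) * rng.choice((-1.0, 1.0), size=3)
    # background arm activity present in both classes
    bg = np.clip(0.5 + 0.5 * _band_noise(rng, n, fs, (0.02, 0.3), 1.0), 0.0, 1.5)
    activity = np.maximum(env_motion if env_motion is not None else env_grip, bg)
    neutral = np.array([0.10, -0.15, 0.95]) + rng.uniform(-0.05, 0.05, size=3)
    grip_target = neutral + _GRIP_POSTURE_DELTA_G + rng.uniform(-0.05, 0.05, size=3)
    ramp = int(cfg.ramp_s * fs)
    for a in range(3):
        wander = neutral[a] + _band_noise(rng, n, fs, (0.02, 0.3), cfg.acc_wander_g)
        for ev in events:
            s, e = ev["span"]
            seg = _ramped_segment(e - s, ramp)
            wander[s:e] += rng.uniform(0.2, 0.5) * rng.choice((-1.0, 1.0)) * seg * ev["imu"]
        orient = wander * (1 - env_grip) + grip_target[a] * env_grip
        motion = _band_noise(rng, n, fs, (0.5, 3.0), cfg.acc_motion_g) * activity
        trans = np.zeros(n)
        for edge in edges:
            trans += _transient(n, edge, fs, rng, cfg.acc_transient_g)
        acc[a] = np.clip(orient + acc_bias[a] + acc_drift[a] * t + motion + trans
                         + cfg.acc_noise_g * rng.standard_normal(n), -2.0, 2.0)
    for a in range(3):
        base = gyro_bias[a] + gyro_drift[a] * t + cfg.gyro_noise_dps * rng.standard_normal(n)
        motion = _band_noise(rng, n, fs, (0.5, 3.0), cfg.gyro_motion_dps) * activity
        trans = np.zeros(n)
        for edge in edges:
            trans += _transient(n, edge, fs, rng, cfg.gyro_transient_dps)
        gyro[a] = np.clip(base + motion + trans, -500.0, 500.0)
    return acc, gyro


def generate_task(cfg: SynthConfig, subject_id: str = "S01", run: int = 1) -> tuple[RawRecording, GroundTruth]:
    """Generate a task session with marks bracketing each true exertion.

    Exertions are amplitude-modulated band-noise bursts with per-grip
    intensity; the gaps contain non-relevant movements (class 2) with their
    own channel patterns and IMU transients.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, intervals = _grip_intervals(cfg, rng)
    ramp = int(cfg.ramp_s * cfg.fs)
    gains = _channel_gains(cfg) * rng.uniform(*cfg.task_gain_wobble, size=8)

    # per-channel activation in uV: grips (common pattern, per-grip intensity)
    activation = np.zeros((8, n))
    if cfg.emg_offset_uv > 0:
        # residual muscle tone: a per-recording constant level
        level = cfg.emg_offset_uv * rng.uniform(0.4, 1.0)
        activation += level * gains[:, None]
    env_grip = np.zeros(n)
    for start, end in intervals:
        seg = _ramped_segment(end - start, ramp)
        intensity = rng.uniform(*cfg.grip_intensity_range)
        for c in range(8):
            activation[c, start:end] += cfg.emg_burst_amp_uv * gains[c] * intensity * seg
        env_grip[start:end] = np.maximum(env_grip[start:end], seg)
    events = _distractor_events(cfg, rng, intervals, n)
    edges = [s for s, _ in intervals] + [e for _, e in intervals]
    for ev in events:
        s, e = ev["span"]
        seg = _ramped_segment(e - s, ramp)
        for c in range(8):
            activation[c, s:e] += cfg.emg_burst_amp_uv * gains[c] * ev["amp"] * ev["weights"][c] * seg
        edges.append((s + e) // 2)

    # motion intensity while gripping varies and overlaps the background
    # arm-activity range, so posture rather than motion level carries the
    # inertial class information
    env_motion = np.zeros(n)
    for start, end in intervals:
        env_motion[start:end] = env_grip[start:end] * rng.uniform(0.4, 1.0)

    gt_int = ExertionIntervals(list(intervals), provenance="ground_truth")
    labels = gt_int.labels(n)
    emg = _emg_channels(cfg, rng, n, activation, labels == 2)
    acc, gyro = _imu_channels(cfg, rng, n, env_grip, sorted(edges), events,
                              env_motion=env_motion)
    marks: list[tuple[int, int]] = []
    for start, end in intervals:
        marks.append((start, 1))
        marks.append((end, 2))
    rec = RawRecording(emg=emg, acc=acc, gyro=gyro, fs=cfg.fs, marks=marks,
                       subject_id=subject_id, session_kind="Task", run=run)
    return rec, GroundTruth(intervals=gt_int, labels=labels)


def generate_mvc(cfg: SynthConfig, subject_id: str = "S01") -> RawRecording:
    """Generate an MVC calibration session: one sustained maximal-effort
    burst with 5 s of rest padding before and after, no other activity."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))
    fs = cfg.fs
    n = int((cfg.lead_in_s + cfg.mvc_burst_s + cfg.lead_out_s) * fs)
    start = int(cfg.lead_in_s * fs)
    end = start + int(cfg.mvc_burst_s * fs)
    intervals = [(start, end)]
    seg = _ramped_segment(end - start, int(cfg.ramp_s * fs))
    gains = _channel_gains(cfg)
    activation = np.zeros((8, n))
    env_grip = np.zeros(n)
    for c in range(8):
        activation[c, start:end] = cfg.mvc_gain * cfg.emg_burst_amp_uv * gains[c] * seg
    env_grip[start:end] = seg
    labels = ExertionIntervals(intervals, provenance="ground_truth").labels(n)
    emg = _emg_channels(cfg, rng, n, activation, labels == 2)
    acc, gyro = _imu_channels(cfg, rng, n, env_grip, [start, end])
    return RawRecording(emg=emg, acc=acc, gyro=gyro, fs=fs, marks=[],
                        subject_id=subject_id, session_kind="MVC", run=1)


@dataclass
class SubjectData:
    """One subject's MVC calibration plus task runs with ground truth."""

    subject_id: str
    mvc: RawRecording
    tasks: list[tuple[RawRecording, GroundTruth]]


def generate_cohort(n_subjects: int, runs_per_subject: int,
                    cfg: SynthConfig | None = None, seed: int = 0) -> list[SubjectData]:
    """Generate a cohort with per-subject randomized amplitudes and pace.

    Every subject gets their own burst amplitude, baseline-noise level, MVC
    gain and corruption magnitudes drawn around the template ``cfg``; the
    total number of task datasets is ``n_subjects * runs_per_subject``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if runs_per_subject < 1:
        raise ValueError("runs_per_subject must be >= 1")
    template = cfg if cfg is not None else SynthConfig()
    template.validate()
    cohort: list[SubjectData] = []
    for s in range(n_subjects):
        draw_rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        subject_id = f"S{s + 1:02d}"
        subj_cfg = replace(
            template,
            channel_gains=tuple(draw_rng.uniform(*template.channel_gain_range, size=8)),
            emg_burst_amp_uv=draw_rng.uniform(150.0, 450.0),
            baseline_noise_uv=draw_rng.uniform(1.0, 3.5),
            mvc_gain=draw_rng.uniform(1.3, 1.8),
            grip_duration_s=template.grip_duration_s * draw_rng.uniform(0.8, 1.2),
            gap_duration_s=template.gap_duration_s * draw_rng.uniform(0.8, 1.2),
            emg_offset_uv=template.emg_offset_uv * draw_rng.uniform(0.7, 1.5),
            acc_offset_g=template.acc_offset_g * draw_rng.uniform(0.7, 1.5),
            gyro_offset_dps=template.gyro_offset_dps * draw_rng.uniform(0.7, 1.5),
            acc_drift_g_per_s=template.acc_drift_g_per_s * draw_rng.uniform(0.5, 1.5),
            gyro_drift_dps_per_s=template.gyro_drift_dps_per_s * draw_rng.uniform(0.5, 1.5),
        )
        mvc = generate_mvc(replace(subj_cfg, seed=int(draw_rng.integers(2 ** 31))), subject_id)
        tasks = []
        for r in range(runs_per_subject):
            run_cfg = replace(subj_cfg, seed=int(draw_rng.integers(2 ** 31)))
            tasks.append(generate_task(run_cfg, subject_id, run=r + 1))
        cohort.append(SubjectData(subject_id=subject_id, mvc=mvc, tasks=tasks))
    return cohort
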