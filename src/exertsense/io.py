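"""Armband CSV I/O, LSB unit conversion, and event-mark pairing.

The armband streams raw 24-bit sensor counts; physical values are obtained by
multiplying with per-sensor least-significant-bit (LSB) factors:

- sEMG: 0.045 uV / count
- gyroscope: 0.015267 dps / count (range -500..500 dps)
- accelerometer: 0.061035e-3 g / count (range -2..2 g)

The canonical CSV dialect used here is one row per sample with header
``t,ch1..ch8,accX,accY,accZ,gyroX,gyroY,gyroZ,trigger``; the trigger column is
0 except at event marks, where it carries 1 ("beep", exertion starts) or 2
("boop", exertion ends). Other vendor exports can be mapped onto this dialect
with a column-mapping config (see :func:`load_config`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

EMG_LSB_UV = 0.045
GYRO_LSB_DPS = 0.015267
ACC_LSB_G = 0.061035e-3
DEFAULT_FS = 500.0

EMG_COLUMNS = [f"ch{i}" for i in range(1, 9)]
ACC_COLUMNS = ["accX", "accY", "accZ"]
GYRO_COLUMNS = ["gyroX", "gyroY", "gyroZ"]
CSV_COLUMNS = ["t"] + EMG_COLUMNS + ACC_COLUMNS + GYRO_COLUMNS + ["trigger"]

ACC_RANGE_G = 2.0
GYRO_RANGE_DPS = 500.0


class VodCsvError(ValueError):
    """Malformed armband CSV (bad header, row, or cell)."""


class MarkError(ValueError):
    """Invalid event-mark sequence."""


@dataclass
class RawRecording:
    """A calibrated multichannel armband recording.

    ``emg`` is (8, N) in uV, ``acc`` (3, N) in g, ``gyro`` (3, N) in dps.
    ``marks`` is an ordered list of ``(sample_index, value)`` with value 1
    (beep) or 2 (boop). When ``scaled`` is False the arrays hold raw counts
    and physical-range checks are skipped.
    """

    emg: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float = DEFAULT_FS
    marks: list[tuple[int, int]] = field(default_factory=list)
    subject_id: str = ""
    session_kind: str = "Task"
    run: int = 1
    scaled: bool = True

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[0] != 8:
            raise ValueError(f"emg must be (8, N), got {self.emg.shape}")
        if self.acc.shape != (3, self.emg.shape[1]) or self.gyro.shape != (3, self.emg.shape[1]):
            raise ValueError("acc and gyro must be (3, N) with the same N as emg")
        n = self.n_samples
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if self.session_kind not in ("MVC", "Task"):
            raise ValueError(f"session_kind must be 'MVC' or 'Task', got {self.session_kind!r}")
        prev = -1
        for idx, value in self.marks:
            if not (0 <= idx < n):
                raise MarkError(f"mark sample index {idx} outside [0, {n})")
            if idx <= prev:
                raise MarkError("mark sample indices must be strictly increasing")
            if value not in (1, 2):
                raise MarkError(f"mark value {value} outside {{1, 2}}")
            prev = idx
        if self.scaled:
            # tiny slack for float rounding at the range edge
            if np.any(np.abs(self.acc) > ACC_RANGE_G * (1 + 1e-9)):
                raise ValueError("accelerometer values outside [-2, 2] g")
            if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS * (1 + 1e-9)):
                raise ValueError("gyroscope values outside [-500, 500] dps")


@dataclass
class ExertionIntervals:
    """Ordered, non-overlapping half-open [start, end) sample intervals."""

    intervals: list[tuple[int, int]]
    provenance: str = "marks"  # {marks, ground_truth, predicted}

    def __post_init__(self):
        prev_end = -1
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ValueError("intervals must be non-overlapping and increasing")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def labels(self, n_samples: int) -> np.ndarray:
        """Per-sample class labels: 1 inside intervals (exertion), 2 elsewhere."""
        lab = np.full(n_samples, 2, dtype=np.int64)
        for start, end in self.intervals:
            lab[start:min(end, n_samples)] = 1
        return lab


def _default_lsb() -> dict[str, float]:
    return {"emg": EMG_LSB_UV, "gyro": GYRO_LSB_DPS, "acc": ACC_LSB_G}


def load_config(path) -> dict:
    """Load a YAML config with optional ``lsb``, ``fs`` and ``columns`` keys.

    ``lsb`` may override ``emg`` (uV/count), ``gyro`` (dps/count) and ``acc``
    (g/count); ``columns`` maps canonical column names to the names used by a
    non-canonical export.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {"lsb": _default_lsb(), "fs": DEFAULT_FS, "columns": {}}
    if "lsb" in raw:
        cfg["lsb"].update(raw["lsb"])
    if "fs" in raw:
        cfg["fs"] = float(raw["fs"])
    if "columns" in raw:
        cfg["columns"] = dict(raw["columns"])
    return cfg


def read_vod_csv(
    path,
    lsb_scaling: bool = True,
    column_map: dict[str, str] | None = None,
    fs: float = DEFAULT_FS,
    subject_id: str = "",
    session_kind: str = "Task",
    run: int = 1,
    lsb: dict[str, float] | None = None,
) -> RawRecording:
    """Read an armband CSV recording.

    With ``lsb_scaling`` on (default), counts are multiplied by their
    channel-type LSB to obtain uV / g / dps; with it off, raw counts are
    returned unvalidated against physical ranges. ``column_map`` maps
    canonical names to the file's column names.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reported as a parse error
        raise VodCsvError(f"{path}: cannot parse CSV: {exc}") from exc

    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise VodCsvError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise VodCsvError(f"{path}: unknown columns {extra}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise VodCsvError(f"{path}: non-numeric cell at line {row + 2}")

    trig = numeric["trigger"].to_numpy()
    if not np.isin(trig, (0, 1, 2)).all():
        row = int(np.flatnonzero(~np.isin(trig, (0, 1, 2)))[0])
        raise VodCsvError(
            f"{path}: trigger value {trig[row]!r} at line {row + 2} outside {{0, 1, 2}}"
        )
    marks = [(int(i), int(trig[i])) for i in np.flatnonzero(trig != 0)]

    lsb = dict(_default_lsb(), **(lsb or {}))
    emg = numeric[EMG_COLUMNS].to_numpy().T
    acc = numeric[ACC_COLUMNS].to_numpy().T
    gyro = numeric[GYRO_COLUMNS].to_numpy().T
    if lsb_scaling:
        emg = emg * lsb["emg"]
        acc = acc * lsb["acc"]
        gyro = gyro * lsb["gyro"]
    return RawRecording(
        emg=emg, acc=acc, gyro=gyro, fs=fs, marks=marks,
        subject_id=subject_id, session_kind=session_kind, run=run,
        scaled=lsb_scaling,
    )


def write_recording(rec: RawRecording, path, lsb: dict[str, float] | None = None) -> None:
    """Write a recording as a canonical CSV of raw integer counts.

    Physical values are divided by the LSBs and rounded to the nearest count,
    so ``read_vod_csv(write_recording(rec))`` round-trips within half an LSB
    per sample.
    """
    lsb = dict(_default_lsb(), **(lsb or {}))
    n = rec.n_samples
    data = {"t": np.arange(n) / rec.fs}
    if rec.scaled:
        emg, acc, gyro = rec.emg / lsb["emg"], rec.acc / lsb["acc"], rec.gyro / lsb["gyro"]
    else:
        emg, acc, gyro = rec.emg, rec.acc, rec.gyro
    for i, c in enumerate(EMG_COLUMNS):
        data[c] = np.rint(emg[i]).astype(np.int64)
    for i, c in enumerate(ACC_COLUMNS):
        data[c] = np.rint(acc[i]).astype(np.int64)
    for i, c in enumerate(GYRO_COLUMNS):
        data[c] = np.rint(gyro[i]).astype(np.int64)
    trig = np.zeros(n, dtype=np.int64)
    for idx, value in rec.marks:
        trig[idx] = value
    data["trigger"] = trig
    pd.DataFrame(data, columns=CSV_COLUMNS).to_csv(path, index=False)


def pair_marks(marks: list[tuple[int, int]], n_samples: int) -> ExertionIntervals:
    """Pair beep (1) / boop (2) marks into half-open exertion intervals.

    Each mark 1 opens an interval that the next mark 2 closes. A boop with no
    open interval, or a second beep before the previous one closed, raises
    :class:`MarkError`. A trailing unmatched beep closes at ``n_samples``
    with a warning (a session stopped mid-grip).
    """
    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    for idx, value in marks:
        if value == 1:
            if open_start is not None:
                raise MarkError(f"mark 1 at sample {idx} while a grip is already open")
            open_start = idx
        elif value == 2:
            if open_start is None:
                raise MarkError(f"mark 2 at sample {idx} with no open grip")
            intervals.append((open_start, idx))
            open_start = None
        else:
            raise MarkError(f"mark value {value} outside {{1, 2}}")
    if open_start is not None:
        warnings.warn(
            f"trailing unmatched mark 1 at sample {open_start}; "
            f"closing interval at end of recording ({n_samples})",
            stacklevel=2,
        )
        intervals.append((open_start, n_samples))
    return ExertionIntervals(intervals, provenance="marks")
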