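"""Sliding-window time-domain features.

Each processed recording is cut into 125-sample windows with 50 % overlap
(step 63) and each of the 14 signals (8 normalized sEMG envelopes, 3
accelerometer, 3 gyroscope) contributes nine statistics per window — mean,
minimum, maximum, standard deviation, variance, median, range, RMS and
kurtosis — for 126 feature columns, plus the majority class label.

Conventions fixed so an independent formula evaluation matches bit-for-bit:
std/var use the sample (n-1) denominator; kurtosis is the *non-excess*
fourth standardized moment with the biased moment estimator (a normal
window gives ~3); a zero-variance window has kurtosis 0 by convention so
the table stays free of NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sstats

from .pipeline import ProcessedRecording

STAT_NAMES = ["mean", "min", "max", "std", "var", "median", "range", "rms", "kurtosis"]
META_COLUMNS = ["label", "window_start", "subject", "run"]


@dataclass
class WindowSpec:
    """Window size (samples) and overlap fraction; step is derived as
    ``size - floor(overlap * size)`` (125, 0.5 -> step 63)."""

    size: int = 125
    overlap: float = 0.5

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    @property
    def step(self) -> int:
        return self.size - int(np.floor(self.overlap * self.size))


def sliding_windows(n_samples: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open [start, start+size) windows at starts 0, step, 2*step, ...
    while they fit; an empty list (with a warning) if the series is shorter
    than one window."""
    if n_samples < spec.size:
        warnings.warn(
            f"series of {n_samples} samples shorter than window {spec.size}; no windows",
            stacklevel=2)
        return []
    starts = range(0, n_samples - spec.size + 1, spec.step)
    return [(s, s + spec.size) for s in starts]


def window_stats(window_values: np.ndarray) -> np.ndarray:
    """The nine statistics of one window, in :data:`STAT_NAMES` order."""
    x = np.asarray(window_values, dtype=float)
    if x.size == 0:
        raise ValueError("window must be nonempty")
    return _stats_matrix(x[None, :])[0]


def _stats_matrix(wins: np.ndarray) -> np.ndarray:
    """(n_windows, 9) statistics for a stack of windows."""
    mean = wins.mean(axis=1)
    mn = wins.min(axis=1)
    mx = wins.max(axis=1)
    if wins.shape[1] > 1:
        std = wins.std(axis=1, ddof=1)
        var = wins.var(axis=1, ddof=1)
    else:
        std = np.zeros(wins.shape[0])
        var = np.zeros(wins.shape[0])
    med = np.median(wins, axis=1)
    rng = mx - mn
    rms = np.sqrt(np.mean(wins ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant windows trip scipy's precision warning; their kurtosis
        # is mapped to the zero-variance convention below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = sstats.kurtosis(wins, axis=1, fisher=False, bias=True)
    kurt = np.where(np.isfinite(kurt), kurt, 0.0)  # zero-variance convention
    return np.column_stack([mean, mn, mx, std, var, med, rng, rms, kurt])


def label_window(window_span: tuple[int, int], labels_per_sample: np.ndarray) -> int:
    """Majority label of a window: 1 (exertion) if at least half the samples
    are exertion, else 2; the tie goes to exertion (biases toward recall)."""
    start, end = window_span
    seg = np.asarray(labels_per_sample)[start:end]
    return 1 if np.count_nonzero(seg == 1) >= seg.size / 2 else 2


def build_feature_table(processed: ProcessedRecording,
                        spec: WindowSpec = WindowSpec(),
                        signals: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Featurize one processed recording into a windows x features table.

    Columns are ``<signal>_<stat>`` for every signal/statistic pair, plus
    ``label``, ``window_start``, ``subject`` and ``run``. ``signals`` can
    override the default 14-signal set (a warning is issued when the feature
    count differs from 126).
    """
    sigs = signals if signals is not None else processed.signals
    n_feat = len(sigs) * len(STAT_NAMES)
    if n_feat != 126:
        warnings.warn(f"{len(sigs)} signals give {n_feat} feature columns, not 126",
                      stacklevel=2)
    spans = sliding_windows(processed.n_samples, spec)
    columns: dict[str, np.ndarray] = {}
    if spans:
        starts = np.array([s for s, _ in spans])
        for name, series in sigs.items():
            wins = sliding_window_view(np.asarray(series, dtype=float), spec.size)[::spec.step]
            wins = wins[: len(spans)]
            stats = _stats_matrix(wins)
            for j, stat in enumerate(STAT_NAMES):
                columns[f"{name}_{stat}"] = stats[:, j]
        labels = np.array([label_window(span, processed.labels) for span in spans])
    else:
        starts = np.array([], dtype=int)
        labels = np.array([], dtype=int)
        for name in sigs:
            for stat in STAT_NAMES:
                columns[f"{name}_{stat}"] = np.array([])
    df = pd.DataFrame(columns)
    df["label"] = labels
    df["window_start"] = starts
    df["subject"] = processed.subject_id
    df["run"] = processed.run
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything except the metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def merge_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-wise concatenation of feature tables with identical schemas,
    preserving per-row subject/run provenance."""
    if not tables:
        raise ValueError("no tables to merge")
    schema = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=2):
        if list(t.columns) != schema:
            raise ValueError(f"table {i} schema mismatch: {list(t.columns)} != {schema}")
    return pd.concat(tables, ignore_index=True)
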