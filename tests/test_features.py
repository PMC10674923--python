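"""Windowing and time-domain feature extraction against direct formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exertsense import (
    STAT_NAMES,
    WindowSpec,
    apply_treatments,
    build_feature_table,
    feature_columns,
    label_window,
    merge_tables,
    sliding_windows,
    window_stats,
)


def brute_starts(n, size, step):
    starts = []
    s = 0
    while s + size <= n:
        starts.append(s)
        s += step
    return starts


class TestSlidingWindows:
    def test_single_exact_window(self):
        assert sliding_windows(125, WindowSpec()) == [(0, 125)]

    def test_default_spec_on_1000_samples(self):
        spans = sliding_windows(1000, WindowSpec())
        assert WindowSpec().step == 63
        assert len(spans) == 14
        assert spans[-1] == (819, 944)

    def test_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no windows"):
            assert sliding_windows(124, WindowSpec()) == []

    @given(n=st.integers(1, 3000), size=st.integers(1, 200),
           overlap=st.floats(0.0, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_enumeration(self, n, size, overlap):
        spec = WindowSpec(size=size, overlap=overlap)
        if n < size:
            return
        spans = sliding_windows(n, spec)
        assert [s for s, _ in spans] == brute_starts(n, size, spec.step)
        # arithmetic progression, all in bounds
        starts = np.array([s for s, _ in spans])
        if starts.size > 1:
            assert np.all(np.diff(starts) == spec.step)
        assert all(e <= n and e - s == size for s, e in spans)


class TestWindowStats:
    def test_known_small_window_against_formulas(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        got = dict(zip(STAT_NAMES, window_stats(x)))
        mu = 3.0
        var = np.sum((x - mu) ** 2) / 4  # sample variance
        m2 = np.mean((x - mu) ** 2)
        m4 = np.mean((x - mu) ** 4)
        assert got["mean"] == mu and got["min"] == 1 and got["max"] == 5
        assert got["median"] == 3 and got["range"] == 4
        assert got["std"] == pytest.approx(np.sqrt(var))
        assert got["var"] == pytest.approx(var)
        assert got["rms"] == pytest.approx(np.sqrt(np.mean(x ** 2)))
        assert got["kurtosis"] == pytest.approx(m4 / m2 ** 2)

    def test_constant_window_conventions(self):
        got = dict(zip(STAT_NAMES, window_stats(np.full(10, -4.0))))
        assert got["mean"] == -4.0 and got["min"] == -4.0 and got["max"] == -4.0
        assert got["std"] == 0.0 and got["var"] == 0.0 and got["range"] == 0.0
        assert got["rms"] == 4.0
        assert got["kurtosis"] == 0.0  # zero-variance convention

    def test_sign_flip_symmetry(self, rng):
        x = rng.standard_normal(50)
        a = dict(zip(STAT_NAMES, window_stats(x)))
        b = dict(zip(STAT_NAMES, window_stats(-x)))
        assert a["mean"] == pytest.approx(-b["mean"])
        assert a["rms"] == pytest.approx(b["rms"])
        assert a["kurtosis"] == pytest.approx(b["kurtosis"])
        assert a["std"] == pytest.approx(b["std"])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            window_stats(np.array([]))


class TestLabelWindow:
    def test_fully_inside_and_outside(self):
        labels = np.array([2] * 50 + [1] * 50)
        assert label_window((60, 90), labels) == 1
        assert label_window((0, 30), labels) == 2

    def test_exact_tie_goes_to_exertion(self):
        labels = np.array([1] * 5 + [2] * 5)
        assert label_window((0, 10), labels) == 1

    def test_minority_exertion_is_rest(self):
        labels = np.array([1] * 4 + [2] * 6)
        assert label_window((0, 10), labels) == 2


class TestBuildFeatureTable:
    def test_126_feature_columns(self, small_session):
        task, _, mvc = small_session
        table = build_feature_table(apply_treatments(task, mvc, "EFABCD"))
        fc = feature_columns(table)
        assert len(fc) == 126
        signals = {c.rsplit("_", 1)[0] for c in fc}
        assert len(signals) == 14
        for name in signals:
            assert sum(c.startswith(name + "_") for c in fc) == 9

    def test_no_nan_or_inf(self, small_session):
        task, _, mvc = small_session
        table = build_feature_table(apply_treatments(task, mvc, "EFABCD"))
        assert np.isfinite(table[feature_columns(table)].to_numpy()).all()

    def test_single_signal_override_gives_nine_columns(self, small_session):
        task, _, mvc = small_session
        proc = apply_treatments(task, mvc, "ABCD")
        with pytest.warns(UserWarning, match="not 126"):
            table = build_feature_table(proc, signals={"ch1": proc.emg_norm[0]})
        assert len(feature_columns(table)) == 9

    def test_all_rest_recording_labels_all_two(self, small_session):
        task, _, mvc = small_session
        proc = apply_treatments(task, mvc, "EFABCD")
        proc.labels = np.full(proc.n_samples, 2)
        table = build_feature_table(proc)
        assert (table["label"] == 2).all()

    def test_window_starts_align_with_spec(self, small_session):
        task, _, mvc = small_session
        proc = apply_treatments(task, mvc, "ABCD")
        table = build_feature_table(proc)
        spans = sliding_windows(proc.n_samples, WindowSpec())
        assert table["window_start"].tolist() == [s for s, _ in spans]

    def test_feature_values_match_window_stats(self, small_session):
        # spot-check a few windows against the scalar evaluator
        task, _, mvc = small_session
        proc = apply_treatments(task, mvc, "ABCD")
        table = build_feature_table(proc)
        spans = sliding_windows(proc.n_samples, WindowSpec())
        for row in (0, len(spans) // 2, len(spans) - 1):
            s, e = spans[row]
            expected = window_stats(proc.emg_norm[0][s:e])
            got = table.loc[row, [f"ch1_{st}" for st in STAT_NAMES]].to_numpy(dtype=float)
            assert np.allclose(got, expected)


class TestMergeTables:
    def _table(self, rows, subject="S01"):
        return pd.DataFrame({
            "a_mean": np.arange(rows, dtype=float), "label": [2] * rows,
            "window_start": np.arange(rows), "subject": subject, "run": 1,
        })

    def test_row_counts_add_up(self):
        merged = merge_tables([self._table(5), self._table(7, "S02"), self._table(3, "S03")])
        assert len(merged) == 15
        assert set(merged["subject"]) == {"S01", "S02", "S03"}

    def test_single_table_identity(self):
        t = self._table(4)
        assert merge_tables([t]).equals(t)

    def test_schema_mismatch_rejected(self):
        bad = self._table(3).rename(columns={"a_mean": "b_mean"})
        with pytest.raises(ValueError, match="schema mismatch"):
            merge_tables([self._table(3), bad])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_tables([])
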