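"""Factorial treatment experiment: ANOVA decomposition against brute-force
oracles, optimizer behavior, and the design harness."""

import numpy as np
import pandas as pd
import pytest

from exertsense import (
    SynthConfig,
    TreatmentFactorial,
    anova_two_way,
    generate_cohort,
    response_optimizer,
    run_design,
)


def make_responses(cell_values: dict, replicates=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (e, f), mu in cell_values.items():
        for r in range(replicates):
            rows.append({"E": e, "F": f, "replicate": r + 1,
                         "response": mu + noise * rng.standard_normal()})
    return pd.DataFrame(rows)


def brute_ss(responses: pd.DataFrame):
    """Cell-mean decomposition of the balanced 2x2xr design."""
    y = responses["response"].to_numpy()
    grand = y.mean()
    r = len(responses) // 4
    e_means = responses.groupby("E")["response"].mean()
    f_means = responses.groupby("F")["response"].mean()
    cell = responses.groupby(["E", "F"])["response"].mean()
    ss_e = 2 * r * sum((m - grand) ** 2 for m in e_means)
    ss_f = 2 * r * sum((m - grand) ** 2 for m in f_means)
    ss_cells = r * sum((m - grand) ** 2 for m in cell)
    ss_ef = ss_cells - ss_e - ss_f
    fitted = responses.groupby(["E", "F"])["response"].transform("mean").to_numpy()
    ss_err = np.sum((y - fitted) ** 2)
    return ss_e, ss_f, ss_ef, ss_err


class TestAnova:
    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = {c: rng.uniform(0.7, 1.0) for c in [(0, 0), (0, 1), (1, 0), (1, 1)]}
            resp = make_responses(vals, replicates=4, noise=0.02,
                                  seed=int(rng.integers(1000)))
            table = anova_two_way(resp)
            ss_e, ss_f, ss_ef, ss_err = brute_ss(resp)
            assert table.loc["E", "sum_sq"] == pytest.approx(ss_e, rel=1e-9, abs=1e-15)
            assert table.loc["F", "sum_sq"] == pytest.approx(ss_f, rel=1e-9, abs=1e-15)
            assert table.loc["E:F", "sum_sq"] == pytest.approx(ss_ef, rel=1e-9, abs=1e-12)
            assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err, rel=1e-9)
            # exact partition of the total SS
            total = np.sum((resp["response"] - resp["response"].mean()) ** 2)
            assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_least_squares_cell_means_fit(self):
        resp = make_responses({(0, 0): 0.8, (0, 1): 0.85, (1, 0): 0.82, (1, 1): 0.95},
                              replicates=3, noise=0.01, seed=4)
        table = anova_two_way(resp)
        # residual SS from an explicit least-squares fit of the cell-means model
        X = np.column_stack([
            np.ones(len(resp)), resp["E"], resp["F"], resp["E"] * resp["F"]])
        beta, *_ = np.linalg.lstsq(X, resp["response"].to_numpy(), rcond=None)
        resid = resp["response"].to_numpy() - X @ beta
        assert table.loc["Residual", "sum_sq"] == pytest.approx(np.sum(resid ** 2))

    def test_pure_main_effect_sum_of_squares(self):
        # +10 E effect, no noise: SS_E = 12 * 5^2 = 300
        resp = make_responses({(0, 0): 70.0, (0, 1): 70.0, (1, 0): 80.0, (1, 1): 80.0})
        table = anova_two_way(resp)
        assert table.loc["E", "sum_sq"] == pytest.approx(300.0)
        assert table.loc["F", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["E:F", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_all_equal_responses_report_p_one(self):
        resp = make_responses({c: 0.9 for c in [(0, 0), (0, 1), (1, 0), (1, 1)]})
        table = anova_two_way(resp)
        assert (table.loc[["E", "F", "E:F"], "p"] == 1.0).all()
        assert (table.loc[["E", "F", "E:F"], "sum_sq"] == 0.0).all()

    def test_strong_effects_are_significant(self):
        resp = make_responses({(0, 0): 0.70, (0, 1): 0.80, (1, 0): 0.78, (1, 1): 0.95},
                              replicates=3, noise=0.005, seed=2)
        table = anova_two_way(resp)
        assert (table.loc[["E", "F", "E:F"], "p"] < 0.01).all()

    def test_degrees_of_freedom(self):
        resp = make_responses({c: 0.9 for c in [(0, 0), (0, 1), (1, 0), (1, 1)]},
                              replicates=5, noise=0.01, seed=1)
        table = anova_two_way(resp)
        assert table.loc["E", "df"] == 1
        assert table.loc["Residual", "df"] == 4 * (5 - 1)

    def test_unbalanced_rejected(self):
        resp = make_responses({c: 0.9 for c in [(0, 0), (0, 1), (1, 0), (1, 1)]})
        with pytest.raises(ValueError, match="unbalanced"):
            anova_two_way(resp.iloc[:-1])

    def test_missing_cell_rejected(self):
        resp = make_responses({(0, 0): 0.9, (0, 1): 0.9, (1, 0): 0.9})
        with pytest.raises(ValueError, match="cells"):
            anova_two_way(resp)


class TestResponseOptimizer:
    def test_argmax_cell_selected(self):
        resp = make_responses({(0, 0): 0.70, (0, 1): 0.75, (1, 0): 0.80, (1, 1): 0.93})
        sol = response_optimizer(resp)
        assert (sol["E"], sol["F"]) == (1, 1)
        assert sol["fit"] == pytest.approx(0.93)

    def test_all_equal_ties_to_neither_applied_with_warning(self):
        resp = make_responses({c: 0.9 for c in [(0, 0), (0, 1), (1, 0), (1, 1)]})
        with pytest.warns(UserWarning, match="tie"):
            sol = response_optimizer(resp)
        assert (sol["E"], sol["F"]) == (0, 0)

    def test_ci_contains_fit_and_shrinks_with_replicates(self):
        vals = {(0, 0): 0.70, (0, 1): 0.75, (1, 0): 0.80, (1, 1): 0.93}
        widths = []
        for reps in (3, 12):
            sol = response_optimizer(make_responses(vals, replicates=reps,
                                                    noise=0.01, seed=6))
            lo, hi = sol["ci"]
            assert lo <= sol["fit"] <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestDesignHarness:
    @pytest.fixture(scope="class")
    def tiny_cohort(self):
        cfg = SynthConfig(n_grips=2, grip_duration_s=1.0, gap_duration_s=1.0,
                          lead_in_s=2.0, lead_out_s=2.0)
        return generate_cohort(2, 1, cfg, seed=5)

    def test_design_size_and_determinism(self, tiny_cohort):
        resp = run_design(tiny_cohort, replicates=2, seed=0, folds=3)
        assert len(resp) == 8  # 4 cells x 2 replicates
        assert set(map(tuple, resp[["E", "F"]].drop_duplicates().to_numpy())) == {
            (0, 0), (0, 1), (1, 0), (1, 1)}
        again = run_design(tiny_cohort, replicates=2, seed=0, folds=3)
        assert np.allclose(resp["response"], again["response"])
        orderings = dict(zip(map(tuple, resp[["E", "F"]].to_numpy()), resp["ordering"]))
        assert orderings[(1, 1)] == "EFABCD" and orderings[(0, 0)] == "ABCD"

    def test_fit_returns_anova_and_optimum(self, tiny_cohort):
        results = TreatmentFactorial.from_cohort(tiny_cohort, replicates=2,
                                                 seed=0, folds=3).fit()
        assert set(results.anova.index) == {"E", "F", "E:F", "Residual"}
        assert results.optimum["E"] in (0, 1) and results.optimum["F"] in (0, 1)
        assert "optimum" in results.summary()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            TreatmentFactorial(pd.DataFrame({"E": [0], "response": [0.9]}))
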