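"""Two-factor factorial treatment experiment.

A 2x2 design over treatment E (offset removal on normalized sEMG) and
treatment F (zero calibration of inertial channels), each level run
``replicates`` times: the full chain is executed per design-table cell, the
feature tables merged, and a quadratic-kernel SVM trained; the response is
the cross-validated training accuracy (a proportion). Replicates re-seed the
cross-validation folds over the same merged table — the only stochastic
element of the trained response. A fixed-effects two-way ANOVA with
interaction (alpha = 0.05) tests the factors, and the response optimizer
picks the cell with the maximal fitted mean, with a pooled-error t-interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats

from .classify import ExertionQSVM
from .features import WindowSpec
from .study import featurize_cohort
from .synth import SubjectData

#: Design-table cells: (E applied, F applied) -> treatment ordering.
DESIGN_CELLS: dict[tuple[int, int], str] = {
    (0, 0): "ABCD",
    (1, 0): "EABCD",
    (0, 1): "FABCD",
    (1, 1): "EFABCD",
}


def run_design(cohort: list[SubjectData], replicates: int = 3, seed: int = 0,
               folds: int = 5, spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Execute pipeline -> features -> QSVM for all 4 cells x replicates.

    Returns a tidy responses frame with columns ``E``, ``F``, ``replicate``,
    ``ordering`` and ``response`` (CV training accuracy as a proportion).
    The expensive signal processing runs once per cell; replicates vary the
    CV fold seed.
    """
    rows = []
    for (e, f), ordering in DESIGN_CELLS.items():
        table = featurize_cohort(cohort, ordering, spec)
        model = ExertionQSVM(table)
        for rep in range(replicates):
            res = model.fit(folds=folds, seed=seed + rep)
            rows.append({"E": e, "F": f, "replicate": rep + 1,
                         "ordering": ordering, "response": res.cv_accuracy})
    return pd.DataFrame(rows)


def _check_balanced(responses: pd.DataFrame) -> int:
    counts = responses.groupby(["E", "F"]).size()
    if set(counts.index) != {(0, 0), (0, 1), (1, 0), (1, 1)}:
        raise ValueError("responses must cover all four (E, F) cells")
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced design: cell counts {counts.to_dict()}")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    return r


def anova_two_way(responses: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction on a balanced 2x2xr design.

    Returns a table indexed by E, F, E:F, Residual with columns ``sum_sq``,
    ``df``, ``F`` and ``p``. When the responses carry no variation at all,
    the F statistics are 0 and p-values reported as 1.
    """
    r = _check_balanced(responses)
    y = responses["response"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        idx = ["E", "F", "E:F", "Residual"]
        return pd.DataFrame(
            {"sum_sq": [0.0] * 4, "df": [1.0, 1.0, 1.0, 4.0 * (r - 1)],
             "F": [0.0, 0.0, 0.0, np.nan], "p": [1.0, 1.0, 1.0, np.nan]},
            index=idx)
    fit = smf.ols("response ~ C(E) * C(F)", data=responses).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index={"C(E)": "E", "C(F)": "F", "C(E):C(F)": "E:F"})
    table = table.rename(columns={"PR(>F)": "p"})
    # zero-variation effects: report p = 1 rather than NaN
    mask = table["sum_sq"].abs() < 1e-30
    table.loc[mask & (table.index != "Residual"), ["F", "p"]] = [0.0, 1.0]
    return table[["sum_sq", "df", "F", "p"]]


def response_optimizer(responses: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cell with the maximal fitted (cell-mean) response, its fit, and the
    (1 - alpha) pooled-error confidence interval for that cell mean.

    Ties break deterministically to the first cell in (E, F) lexicographic
    order — i.e. (not applied, not applied) — with a warning.
    """
    r = _check_balanced(responses)
    means = responses.groupby(["E", "F"])["response"].mean()
    cells = [(0, 0), (0, 1), (1, 0), (1, 1)]
    values = np.array([means[c] for c in cells])
    best = int(np.argmax(values))
    if np.sum(np.isclose(values, values[best])) > 1:
        warnings.warn("tie among cell means; picking the first in (E, F) order",
                      stacklevel=2)
        best = int(np.flatnonzero(np.isclose(values, values[best]))[0])
    e, f = cells[best]
    fit_value = float(values[best])
    # pooled error variance from within-cell deviations
    resid = responses["response"] - responses.groupby(["E", "F"])["response"].transform("mean")
    df_err = 4 * (r - 1)
    mse = float((resid ** 2).sum() / df_err)
    half = sstats.t.ppf(1 - alpha / 2, df_err) * np.sqrt(mse / r)
    return {
        "E": e, "F": f, "fit": fit_value,
        "ci": (fit_value - half, fit_value + half),
        "alpha": alpha,
    }


class TreatmentFactorial:
    """Factorial treatment-selection experiment as a model object.

    Build from a tidy responses frame (columns ``E``, ``F``, ``response``)
    or run the full harness on a synthetic cohort with
    :meth:`from_cohort`. ``fit`` performs the ANOVA and response
    optimization and returns a :class:`FactorialResults`.
    """

    def __init__(self, responses: pd.DataFrame):
        missing = [c for c in ("E", "F", "response") if c not in responses.columns]
        if missing:
            raise ValueError(f"responses frame lacks columns {missing}")
        self.responses = responses.copy()

    @classmethod
    def from_cohort(cls, cohort: list[SubjectData], replicates: int = 3,
                    seed: int = 0, folds: int = 5,
                    spec: WindowSpec = WindowSpec()) -> "TreatmentFactorial":
        return cls(run_design(cohort, replicates=replicates, seed=seed,
                              folds=folds, spec=spec))

    def fit(self, alpha: float = 0.05) -> "FactorialResults":
        anova = anova_two_way(self.responses, alpha=alpha)
        optimum = response_optimizer(self.responses, alpha=alpha)
        cell_means = self.responses.groupby(["E", "F"])["response"].mean()
        return FactorialResults(responses=self.responses, anova=anova,
                                cell_means=cell_means, optimum=optimum, alpha=alpha)


@dataclass
class FactorialResults:
    """ANOVA table, cell means and the accuracy-maximizing treatment cell."""

    responses: pd.DataFrame
    anova: pd.DataFrame
    cell_means: pd.Series
    optimum: dict
    alpha: float

    def summary(self) -> str:
        applied = {0: "not applied", 1: "applied"}
        lines = ["Two-factor treatment experiment (response: CV training accuracy)",
                 "", "ANOVA (alpha = {:.2f})".format(self.alpha),
                 self.anova.to_string(float_format=lambda v: f"{v:.6g}"), "",
                 "cell means:"]
        for (e, f), m in self.cell_means.items():
            lines.append(f"  E {applied[e]:>11}, F {applied[f]:>11}: {m:.4f}")
        lo, hi = self.optimum["ci"]
        lines.append(
            f"optimum: E {applied[self.optimum['E']]}, F {applied[self.optimum['F']]}; "
            f"fit {self.optimum['fit']:.4f}, "
            f"{100 * (1 - self.alpha):.0f}% CI ({lo:.6f}; {hi:.6f})")
        return "\n".join(lines)
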