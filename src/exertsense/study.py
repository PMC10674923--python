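"""Cohort-level harnesses: featurize a cohort and run held-out evaluation.

The study design mirrors the field protocol: each subject contributes an MVC
calibration plus task runs; training merges the feature tables of the
training subjects' runs; testing evaluates the fitted detector per-window on
a subject never seen in training.
"""

from __future__ import annotations

import pandas as pd

from .classify import ExertionQSVM, MetricsReport
from .features import WindowSpec, build_feature_table, merge_tables  # noqa: F401
from .pipeline import apply_treatments
from .synth import SubjectData


def featurize_cohort(cohort: list[SubjectData], ordering: str = "EFABCD",
                     spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Process every task run of a cohort under ``ordering`` and merge the
    per-run feature tables (treatments C + D)."""
    tables = []
    for subject in cohort:
        for task, _gt in subject.tasks:
            processed = apply_treatments(task, subject.mvc, ordering)
            tables.append(build_feature_table(processed, spec))
    return merge_tables(tables)


def holdout_metrics(cohort: list[SubjectData], test_subject_id: str,
                    ordering: str = "EFABCD", folds: int = 5, seed: int = 0,
                    spec: WindowSpec = WindowSpec()) -> tuple[MetricsReport, float]:
    """Train on every subject except ``test_subject_id``; evaluate per-window
    on the held-out subject's runs.

    Returns the held-out :class:`MetricsReport` (pooled over the subject's
    runs) and the cross-validated training accuracy.
    """
    train = [s for s in cohort if s.subject_id != test_subject_id]
    test = [s for s in cohort if s.subject_id == test_subject_id]
    if not test:
        raise ValueError(f"subject {test_subject_id!r} not in cohort")
    if not train:
        raise ValueError("cohort must contain at least one training subject")
    train_table = featurize_cohort(train, ordering, spec)
    results = ExertionQSVM(train_table).fit(folds=folds, seed=seed)
    test_table = featurize_cohort(test, ordering, spec)
    return results.evaluate(test_table), results.cv_accuracy


# --- desk-scale reference study -------------------------------------------
#
# The reference experiment the package reproduces end to end, at sizes
# suited to a single CPU: 8 training subjects + 1 held out with two runs
# each for the selected chain on clean sessions, a heavier-corruption cohort
# of 14 + 1 subjects with shorter runs for the baseline-chain contrast, and
# the 2x2x3 factorial on the corrupted cohort's training subjects.

BEST_N_SUBJECTS = 9       # 8 train + 1 held out
CORRUPT_N_SUBJECTS = 15   # 14 train + 1 held out
RUNS_PER_SUBJECT = 2
N_COHORT_SEEDS = 3


def corrupted_study_config(**overrides) -> "SynthConfig":
    """Corrupted-cohort conditions: heavy-corruption preset with shorter runs
    so the design can afford more recordings."""
    from .synth import SynthConfig

    base = dict(grip_duration_s=1.5, gap_duration_s=1.5)
    base.update(overrides)
    return SynthConfig.corrupted(**base)


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31))


def best_treatment_study(seed: int) -> list[MetricsReport]:
    """Selected chain (E, F, A, B, C, D) on clean cohorts: held-out metrics
    for ``N_COHORT_SEEDS`` independent cohort draws."""
    from .synth import SynthConfig, generate_cohort

    reports = []
    for k in range(N_COHORT_SEEDS):
        s = _derive_seed(seed, k)
        cohort = generate_cohort(BEST_N_SUBJECTS, RUNS_PER_SUBJECT,
                                 SynthConfig(), seed=s)
        rep, _cv = holdout_metrics(cohort, cohort[-1].subject_id, "EFABCD", seed=s)
        reports.append(rep)
    return reports


def corrupted_cohort(seed: int):
    from .synth import generate_cohort

    return generate_cohort(CORRUPT_N_SUBJECTS, RUNS_PER_SUBJECT,
                           corrupted_study_config(), seed=_derive_seed(seed, 100))


N_WORST_HOLDOUT = 3


def worst_treatment_study(cohort, seed: int) -> MetricsReport:
    """Baseline chain (filtering + direct normalization) on the corrupted
    cohort: leave-one-subject-out over the last ``N_WORST_HOLDOUT`` subjects
    with pooled confusion counts.

    Pooling several held-out subjects keeps the estimate from hinging on a
    single wearer's corruption draw.
    """
    tables = {s.subject_id: featurize_cohort([s], "worst") for s in cohort}
    fold_seed = _derive_seed(seed, 200)
    tp = fn = fp = tn = 0
    for subject in cohort[-N_WORST_HOLDOUT:]:
        train = merge_tables([t for sid, t in tables.items()
                              if sid != subject.subject_id])
        results = ExertionQSVM(train).fit(seed=fold_seed)
        rep = results.evaluate(tables[subject.subject_id])
        tp, fn, fp, tn = tp + rep.tp, fn + rep.fn, fp + rep.fp, tn + rep.tn
    return MetricsReport(tp=tp, fn=fn, fp=fp, tn=tn)
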