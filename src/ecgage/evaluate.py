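"""Evaluation: macro-AUC, accuracy, test-set bootstrap, class consolidation.

The headline metric is the macro-averaged one-vs-rest AUC over age groups,
which is robust to the cohort's class imbalance; uncertainty comes from
subject-level bootstrap resampling of the test set, reported as the 2.5
and 97.5 empirical percentiles.  For comparison with coarse feature-based
classifiers, 15-group predictions can be consolidated onto 4 contiguous
broad categories by summing probabilities within each category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .age_groups import DEFAULT_CONSOLIDATION, N_AGE_GROUPS, consolidation_map


@dataclass
class MetricReport:
    macro_auc: float
    per_group_auc: dict  # group -> AUC (groups present in the truth)
    accuracy: float
    n_subjects: int


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def macro_auc(y_true: np.ndarray, proba: np.ndarray) -> tuple:
    """One-vs-rest AUC per group present in the truth (ties count half) and
    their unweighted mean; absent groups are excluded.  ``proba`` columns
    index the groups 0..K-1."""
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("macro-AUC needs at least 2 classes in the truth")
    per_group = {}
    for g in present:
        per_group[int(g)] = float(roc_auc_score((y_true == g).astype(int), proba[:, g]))
    return float(np.mean(list(per_group.values()))), per_group


def accuracy(y_true: np.ndarray, proba: np.ndarray) -> float:
    """Fraction of subjects whose argmax class (lowest-index tie-break)
    equals the truth."""
    y_true = np.asarray(y_true)
    return float(np.mean(np.argmax(proba, axis=1) == y_true))


def metric_report(y_true: np.ndarray, proba: np.ndarray) -> MetricReport:
    m, per = macro_auc(y_true, proba)
    return MetricReport(
        macro_auc=m, per_group_auc=per,
        accuracy=accuracy(y_true, proba), n_subjects=len(y_true),
    )


def bootstrap_ci(
    y_true: np.ndarray,
    proba: np.ndarray,
    metric=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap over subjects; replicates on which the metric is
    undefined (single class drawn) are redrawn and counted."""
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if len(y_true) < 10:
        raise ValueError("bootstrap needs at least 10 subjects")
    if metric is None:
        metric = lambda y, p: macro_auc(y, p)[0]  # noqa: E731
    rng = np.random.default_rng(seed)
    point = float(metric(y_true, proba))
    scores = []
    n_redrawn = 0
    while len(scores) < n_boot:
        idx = rng.integers(0, len(y_true), size=len(y_true))
        try:
            scores.append(float(metric(y_true[idx], proba[idx])))
        except ValueError:
            n_redrawn += 1
            if n_redrawn > 100 * n_boot:
                raise RuntimeError("bootstrap cannot draw valid replicates")
    lower, upper = np.percentile(scores, [2.5, 97.5])
    return BootstrapCI(
        point=point, lower=float(lower), upper=float(upper),
        n_boot=n_boot, seed=seed, n_redrawn=n_redrawn,
    )


def consolidate_age_groups(
    labels15: np.ndarray,
    probabilities15: np.ndarray,
    partition: tuple = DEFAULT_CONSOLIDATION,
) -> tuple:
    """Map 15-group labels/probabilities onto the broad categories by summing
    probabilities within each contiguous category."""
    mapping = np.array(consolidation_map(partition))
    labels15 = np.asarray(labels15)
    probabilities15 = np.asarray(probabilities15, dtype=float)
    if probabilities15.shape[1] != N_AGE_GROUPS:
        raise ValueError("expected 15 probability columns")
    labels4 = mapping[labels15]
    n_cat = len(partition)
    probs4 = np.zeros((len(probabilities15), n_cat))
    for cat in range(n_cat):
        probs4[:, cat] = probabilities15[:, mapping == cat].sum(axis=1)
    return labels4, probs4
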