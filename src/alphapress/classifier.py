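"""Single-trial confidence decoding from a scalar neural value.

The decoder is deliberately simple: the training trials' neural values form
a sure and an unsure distribution; a criterion c ∈ [0, 1] interpolates a
threshold between the unsure median (c = 0) and the sure median (c = 1),
and a test value above the threshold is predicted "sure". Accuracy is
assessed by leave-one-out cross-validation, reported per class and as the
unweighted mean of the two class accuracies; significance comes from a
label-permutation null summarized by a fitted normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "ClassifierModel",
    "LooResult",
    "fit",
    "predict",
    "loo_accuracy",
    "criterion_sweep",
    "permutation_test",
]


@dataclass(frozen=True)
class ClassifierModel:
    """Class medians and the interpolated decision threshold."""

    median_sure: float
    median_unsure: float
    criterion: float

    @property
    def threshold(self) -> float:
        return self.median_unsure + self.criterion * (self.median_sure - self.median_unsure)


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out accuracies (percent) at one criterion."""

    criterion: float
    accuracy_sure: float
    accuracy_unsure: float
    n_sure: int
    n_unsure: int
    n_skipped_folds: int = 0

    @property
    def average(self) -> float:
        """Unweighted mean of the two class accuracies."""
        return (self.accuracy_sure + self.accuracy_unsure) / 2.0


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        return labels == "sure"
    return labels.astype(bool)


def fit(values: np.ndarray, labels, criterion: float = 0.55) -> ClassifierModel:
    """Store the sure/unsure medians of the training values."""
    values = np.asarray(values, dtype=float)
    sure = _as_bool_labels(labels)
    if sure.sum() < 2 or (~sure).sum() < 2:
        raise ValueError("need at least 2 trials per confidence class")
    return ClassifierModel(
        median_sure=float(np.median(values[sure])),
        median_unsure=float(np.median(values[~sure])),
        criterion=float(criterion),
    )


def predict(value: float | np.ndarray, model: ClassifierModel):
    """Predict sure iff the value exceeds the threshold (ties → unsure)."""
    above = np.asarray(value, dtype=float) > model.threshold
    out = np.where(above, "sure", "unsure")
    return out.item() if out.ndim == 0 else out


def loo_accuracy(values: np.ndarray, labels, criterion: float = 0.55) -> LooResult:
    """Leave-one-out accuracy: refit the medians on N−1 trials, test the Nth.

    A training fold may hold as little as one trial of a class (its median
    is that value); folds whose training split loses a class entirely are
    skipped with a warning and counted in ``n_skipped_folds``. Class
    accuracies are percentages over the tested trials of each class; the
    headline number is their unweighted mean.
    """
    values = np.asarray(values, dtype=float)
    sure = _as_bool_labels(labels)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 trials for leave-one-out")
    correct = {True: 0, False: 0}
    tested = {True: 0, False: 0}
    skipped = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        s_train = sure[train]
        if s_train.all() or (~s_train).all():
            skipped += 1
            continue
        v_train = values[train]
        m_sure = float(np.median(v_train[s_train]))
        m_unsure = float(np.median(v_train[~s_train]))
        threshold = m_unsure + criterion * (m_sure - m_unsure)
        pred_sure = values[i] > threshold
        tested[bool(sure[i])] += 1
        if pred_sure == bool(sure[i]):
            correct[bool(sure[i])] += 1
    if skipped:
        warnings.warn(f"{skipped} leave-one-out folds lost a class and were skipped", stacklevel=2)
    if tested[True] == 0 or tested[False] == 0:
        raise ValueError("a confidence class was never tested")
    return LooResult(
        criterion=float(criterion),
        accuracy_sure=100.0 * correct[True] / tested[True],
        accuracy_unsure=100.0 * correct[False] / tested[False],
        n_sure=tested[True],
        n_unsure=tested[False],
        n_skipped_folds=skipped,
    )


def criterion_sweep(values: np.ndarray, labels, grid: np.ndarray | None = None) -> dict:
    """Leave-one-out class accuracies across a grid of criteria.

    Returns ``{"criterion": grid, "sure": ..., "unsure": ..., "average": ...}``
    (percent), mirroring the accuracy-versus-criterion curves used to choose
    an operating point.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("criterion grid must lie within [0, 1]")
    results = [loo_accuracy(values, labels, c) for c in grid]
    return {
        "criterion": grid,
        "sure": np.array([r.accuracy_sure for r in results]),
        "unsure": np.array([r.accuracy_unsure for r in results]),
        "average": np.array([r.average for r in results]),
    }


def permutation_test(
    values: np.ndarray,
    labels,
    criterion: float = 0.55,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Label-permutation null for the leave-one-out average accuracy.

    Labels are reshuffled ``n_perm`` times (within the given trial set — a
    single subject's trials in the per-subject analysis); each shuffle gets
    the full leave-one-out evaluation. The null is summarized by a fitted
    normal, and the observed accuracy's p-value is that normal's upper tail.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sure = _as_bool_labels(labels)
    observed = loo_accuracy(values, sure, criterion).average
    null = np.empty(n_perm)
    for j in range(n_perm):
        null[j] = loo_accuracy(values, rng.permutation(sure), criterion).average
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    p = float(scipy.stats.norm.sf(observed, loc=mu, scale=sd)) if sd > 0 else float(observed <= mu)
    return {
        "observed": float(observed),
        "null_mean": mu,
        "null_sd": sd,
        "p_value": p,
        "null": null,
    }
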