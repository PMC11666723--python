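"""Pseudo-trial bootstrap linear decoding of binary feature options.

For every left-out trial, the remaining trials of each class are
randomly partitioned into three folds and fold-averaged into
pseudo-trials; two of the three pseudo-trials per class (rotated across
bootstrap repeats) form the training set of a linear classifier, which
then labels the left-out trial.  Accuracy is the fraction of correct
classifications over ``n_boot`` repeats, computed independently per
time point.

The default classifier is the closed-form mean-difference separator
(the heavily regularized limit of a linear max-margin/logistic model);
with four training samples the solver choice is immaterial, and the
closed form keeps the bootstrap loop vectorizable.  An SVM solver is
available for cross-checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .errors import ConfigurationError

__all__ = ["DecodingResult", "pseudo_trial_decode", "condition_decoding_curves"]


@dataclass
class DecodingResult:
    """Per-trial bootstrapped accuracy estimates over time."""

    accuracy: np.ndarray              # trial x time, in [0, 1]
    times: np.ndarray
    labels: np.ndarray
    n_boot: int
    n_folds: int
    classifier: str
    trial_info: "object | None" = None  # optional DataFrame of condition labels


def _svm_accuracy(train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray,
                  test_y: int) -> float:
    from sklearn.svm import LinearSVC

    clf = LinearSVC(C=1.0, dual=True, max_iter=10_000)
    clf.fit(train_x, train_y)
    return float(clf.predict(test_x[None, :])[0] == test_y)


def pseudo_trial_decode(
    patterns: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 100,
    n_folds: int = 3,
    seed: int = 0,
    classifier: str = "mean-difference",
    trial_info=None,
) -> DecodingResult:
    """Leave-one-trial-out pseudo-trial bootstrap decoding.

    Parameters
    ----------
    patterns
        trial x feature or trial x feature x time array.
    labels
        Binary class labels, one per trial.
    classifier
        ``'mean-difference'`` (closed form, default) or ``'svm'``.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim == 2:
        patterns = patterns[:, :, None]
    if patterns.ndim != 3:
        raise ConfigurationError("patterns must be trial x feature [x time]")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ConfigurationError(f"exactly two classes required, got {classes.size}")
    n_trials, _, n_time = patterns.shape
    if labels.size != n_trials:
        raise ConfigurationError("labels do not match the trial axis")

    y = (labels == classes[1]).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds * 2 + 1:
        raise ConfigurationError(
            f"need >= {n_folds * 2 + 1} trials per class, got {counts.tolist()}")
    # tolerance: up to 4:1 imbalance handled by stratified subsampling of folds
    if counts.max() > 4 * counts.min():
        warnings.warn("severe class imbalance; folds subsample the larger class",
                      stacklevel=2)

    rng = child_rng(seed, "decoding")
    class_idx = [np.flatnonzero(y == c) for c in (0, 1)]
    accuracy = np.zeros((n_trials, n_time))

    for t in range(n_trials):
        # training pools exclude the left-out trial entirely (no leakage)
        pools = [idx[idx != t] for idx in class_idx]
        pool_sizes = [p.size for p in pools]
        per_fold = min(pool_sizes) // n_folds
        use = [n_folds * per_fold] * 2

        for ci in (0, 1):
            if pools[ci].size == 0:
                raise ConfigurationError("empty training pool")

        correct = np.zeros(n_time)
        test = patterns[t]  # feature x time
        for _ in range(n_boot):
            pseudo = []  # per class: 2 x feature x time training pseudo-trials
            for ci in (0, 1):
                perm = rng.permutation(pools[ci])[: use[ci]]
                folds = perm.reshape(n_folds, per_fold)
                fold_means = patterns[folds].mean(axis=1)  # fold x feature x time
                pick = rng.choice(n_folds, size=2, replace=False)
                pseudo.append(fold_means[pick])
            if classifier == "mean-difference":
                m0, m1 = pseudo[0].mean(axis=0), pseudo[1].mean(axis=0)
                w = m1 - m0
                score = ((test - 0.5 * (m0 + m1)) * w).sum(axis=0)
                pred = (score > 0).astype(int)
                correct += pred == y[t]
            elif classifier == "svm":
                train_y = np.array([0, 0, 1, 1])
                for ti in range(n_time):
                    tx = np.concatenate([pseudo[0][:, :, ti], pseudo[1][:, :, ti]])
                    correct[ti] += _svm_accuracy(tx, train_y, test[:, ti], y[t])
            else:
                raise ConfigurationError(f"unknown classifier {classifier!r}")
        accuracy[t] = correct / n_boot

    return DecodingResult(accuracy=accuracy, times=np.arange(n_time, dtype=float),
                          labels=labels, n_boot=n_boot, n_folds=n_folds,
                          classifier=classifier, trial_info=trial_info)


def condition_decoding_curves(
    result: DecodingResult,
    assignment: np.ndarray,
) -> dict:
    """Average accuracy time courses per condition assignment.

    ``assignment`` holds one condition label per trial (e.g. cued/uncued
    or the load level).  Empty cells are flagged missing rather than
    silently dropped.
    """
    assignment = np.asarray(assignment)
    if assignment.size != result.accuracy.shape[0]:
        raise ConfigurationError("assignment does not match the trial axis")
    out: dict = {"times": result.times, "conditions": {}}
    for cond in np.unique(assignment):
        sel = assignment == cond
        if not sel.any():  # pragma: no cover - np.unique guarantees presence
            out["conditions"][cond] = {"mean": None, "sem": None, "n": 0, "missing": True}
            continue
        acc = result.accuracy[sel]
        out["conditions"][cond] = {
            "mean": acc.mean(axis=0),
            "sem": acc.std(axis=0, ddof=1) / np.sqrt(sel.sum()) if sel.sum() > 1 else
                   np.full(result.times.size, np.nan),
            "n": int(sel.sum()),
            "missing": False,
        }
    return out
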