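"""Leave-one-out cross-validation harness and performance measures.

The positive class is +1 throughout (class C1, benign-like), matching the
dataset labeling convention; sensitivity is therefore the true rate on the
+1 class.  Pass ``positive=-1`` to the report builder to flip to the
clinical (malignant-positive) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .data import LabeledDataset
from .exceptions import ContractError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    acc: float
    auc: float
    sen: float
    spe: float
    counts: ConfusionCounts
    scores: np.ndarray
    labels_true: np.ndarray
    labels_pred: np.ndarray

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "sen": self.sen,
            "spe": self.spe,
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "scores": [float(s) for s in self.scores],
            "labels_true": [int(v) for v in self.labels_true],
            "labels_pred": [int(v) for v in self.labels_pred],
        }


@dataclass(frozen=True)
class RepetitionSummary:
    reports: tuple[EvalReport, ...]
    best: EvalReport
    acc_mean: float
    acc_std: float
    auc_mean: float
    auc_std: float
    hidden_mean: float | None
    hidden_std: float | None
    seeds: tuple[int, ...]


def _check_labels(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (1, -1)).all():
        raise ContractError("labels must be +1 or -1")
    return v.astype(int)


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with +1 as the positive class."""
    yt = _check_labels(labels_true)
    yp = _check_labels(labels_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ContractError("label vectors must be nonempty and equal-length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise ContractError("accuracy of an empty confusion table is undefined")
    return (c.tp + c.tn) / c.total


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP))."""
    if c.tp + c.fn == 0:
        raise ContractError("sensitivity undefined: no positive-class cases")
    if c.tn + c.fp == 0:
        raise ContractError("specificity undefined: no negative-class cases")
    return c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp)


def auc(scores: np.ndarray, labels_true: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted as 1/2.

    Equals the fraction of (positive, negative) case pairs in which the
    positive case received the higher score.
    """
    s = np.asarray(scores, dtype=float)
    yt = _check_labels(labels_true)
    if s.shape != yt.shape:
        raise ContractError("scores and labels must be equal-length")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == -1))
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[yt == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def report_from_scores(
    scores: np.ndarray,
    labels_true: np.ndarray,
    labels_pred: np.ndarray,
    positive: int = 1,
) -> EvalReport:
    """Assemble the four measures from per-case scores and labels."""
    yt = _check_labels(labels_true)
    yp = _check_labels(labels_pred)
    s = np.asarray(scores, dtype=float)
    if positive == -1:
        yt, yp, s = -yt, -yp, -s
    c = confusion(yt, yp)
    sen, spe = sensitivity_specificity(c)
    return EvalReport(
        acc=accuracy(c),
        auc=auc(s, yt),
        sen=sen,
        spe=spe,
        counts=c,
        scores=s,
        labels_true=yt,
        labels_pred=yp,
    )


#: A fold hook maps (train_idx, test_idx) -> (X_train, t_train, x_test);
#: it lets callers re-run trained preprocessing (e.g. threshold selection)
#: on the training portion of each fold only.
FoldHook = Callable[[np.ndarray, int], tuple[np.ndarray, np.ndarray, np.ndarray]]


def loocv(
    data: LabeledDataset,
    make_classifier: Callable[[], object],
    fold_hook: FoldHook | None = None,
    positive: int = 1,
) -> EvalReport:
    """Leave-one-out cross-validation.

    Each case is held out once; the classifier (a fresh instance from
    ``make_classifier``) is fitted on the remaining N-1 cases and scores the
    held-out case.  Measures are computed once over all N held-out scores.
    """
    if data.n < 3:
        raise ContractError(f"LOO-CV needs N >= 3, got N={data.n}")
    scores = np.empty(data.n)
    preds = np.empty(data.n, dtype=int)
    for i in range(data.n):
        train_idx = np.delete(np.arange(data.n), i)
        if fold_hook is not None:
            X_tr, t_tr, x_te = fold_hook(train_idx, i)
        else:
            X_tr, t_tr, x_te = data.X[train_idx], data.t[train_idx], data.X[i]
        if not (np.any(t_tr == 1) and np.any(t_tr == -1)):
            raise ContractError(f"fold {i}: training portion has a single class")
        clf = make_classifier()
        clf.fit(LabeledDataset(X_tr, t_tr))
        score = float(np.atleast_1d(clf.decision_function(np.atleast_2d(x_te)))[0])
        scores[i] = score
        preds[i] = 1 if score >= 0 else -1
    return report_from_scores(scores, data.t, preds, positive=positive)


def repeat_elm_loocv(
    data: LabeledDataset,
    make_classifier: Callable[[int], object],
    reps: int = 30,
    base_seed: int = 0,
    fold_hook: FoldHook | None = None,
    positive: int = 1,
) -> RepetitionSummary:
    """Run LOO-CV ``reps`` times with seeds base_seed..base_seed+reps-1.

    ``make_classifier(seed)`` must return a fresh classifier whose random
    draws are governed by the seed.  Summarizes best (max ACC, ties by AUC),
    mean, and sample (n-1) standard deviation of ACC/AUC and of the fitted
    hidden-neuron count where the classifier exposes one.
    """
    if reps < 1:
        raise ContractError(f"reps must be >= 1, got {reps}")
    seeds = tuple(range(base_seed, base_seed + reps))
    reports: list[EvalReport] = []
    hidden: list[float] = []
    for seed in seeds:
        fold_clfs: list[object] = []

        def factory(seed=seed, fold_clfs=fold_clfs):
            clf = make_classifier(seed)
            fold_clfs.append(clf)
            return clf

        reports.append(loocv(data, factory, fold_hook=fold_hook, positive=positive))
        counts = [
            float(c.n_hidden_)
            for c in fold_clfs
            if getattr(c, "n_hidden_", None) is not None
        ]
        if counts:  # per-repetition hidden size = mean over the N folds
            hidden.append(float(np.mean(counts)))
    accs = np.array([r.acc for r in reports])
    aucs = np.array([r.auc for r in reports])
    best = max(reports, key=lambda r: (r.acc, r.auc))
    std = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0  # noqa: E731
    return RepetitionSummary(
        reports=tuple(reports),
        best=best,
        acc_mean=float(accs.mean()),
        acc_std=std(accs),
        auc_mean=float(aucs.mean()),
        auc_std=std(aucs),
        hidden_mean=float(np.mean(hidden)) if hidden else None,
        hidden_std=std(np.array(hidden)) if hidden else None,
        seeds=seeds,
    )
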