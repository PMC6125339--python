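"""Feasible-vs-infeasible classification of sampled parameter vectors.

The sampled feasible set has non-convex geometry that is expensive to map
explicitly in 27 dimensions.  A binary classifier trained on the sampled
labels ("feasible for at least one QOI" vs "feasible for none") tests
whether that geometry carries learnable, non-random structure: a
cross-validated ROC AUC clearly above 0.5 means a decision surface can
stand in for the feasible-set boundary.

ROC construction and AUC are implemented here (not delegated) so that the
trapezoidal area can be checked exactly against the pairwise-comparison
statistic P(score+ > score-) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._rng import substream, substream_seed
from .feasibility import SampleBatch, count_at_least

__all__ = [
    "LabeledSamples",
    "ROCCurve",
    "assemble_classes",
    "downsample",
    "cv_classify",
    "roc_curve",
    "auc",
]


class DegenerateClassError(ValueError):
    """One of the two classes has no members."""


@dataclass(frozen=True)
class LabeledSamples:
    """Parameter vectors with a feasibility label.

    ``labels[i]`` is True exactly when row i is feasible for at least one
    QOI (mask row-sum >= 1).
    """

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        labels = np.asarray(self.labels, dtype=bool).reshape(-1)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X and labels row counts differ")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)

    @property
    def n_feasible(self) -> int:
        return int(self.labels.sum())

    @property
    def n_infeasible(self) -> int:
        return int((~self.labels).sum())


def assemble_classes(batch: SampleBatch) -> LabeledSamples:
    """Label each usable batch row: feasible for >= 1 QOI, or for none."""
    if batch.mask is None:
        raise ValueError("batch has no mask; call apply_bounds first")
    usable = batch.ok
    labels = (batch.mask.sum(axis=1) >= 1) & usable
    data = LabeledSamples(batch.params[usable], labels[usable])
    if data.n_feasible == 0 or data.n_infeasible == 0:
        raise DegenerateClassError(
            f"degenerate classes: {data.n_feasible} feasible, "
            f"{data.n_infeasible} infeasible"
        )
    assert data.n_feasible == count_at_least(batch, 1)
    return data


def downsample(data: LabeledSamples, per_class: int, seed: int) -> LabeledSamples:
    """Balance the classes: ``per_class`` rows each, uniform without replacement."""
    lo = min(data.n_feasible, data.n_infeasible)
    if per_class > lo:
        raise ValueError(
            f"per_class {per_class} exceeds smallest class "
            f"(feasible={data.n_feasible}, infeasible={data.n_infeasible})"
        )
    rng = substream(seed, "class-downsample")
    pos = np.where(data.labels)[0]
    neg = np.where(~data.labels)[0]
    keep = np.concatenate(
        [
            rng.choice(pos, size=per_class, replace=False),
            rng.choice(neg, size=per_class, replace=False),
        ]
    )
    keep.sort()
    return LabeledSamples(data.X[keep], data.labels[keep])


@dataclass(frozen=True)
class ROCCurve:
    """Receiver operating characteristic swept over all score thresholds."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "fpr", "tpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.fpr.shape == self.tpr.shape == self.thresholds.shape):
            raise ValueError("curve arrays must share a shape")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("TPR and FPR must be non-decreasing along the curve")

    @property
    def auc(self) -> float:
        return auc(self)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("threshold,fpr,tpr\n")
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{float(t)!r},{float(f)!r},{float(s)!r}\n")


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC from continuous scores; endpoints (0,0) and (1,1) included.

    TPR = true positives / total positives and FPR = false positives /
    total negatives, swept over every distinct score threshold (predict
    positive when score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateClassError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.where(np.diff(s_sorted))[0]
    cut = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(l_sorted)[cut]
    fp = np.cumsum(~l_sorted)[cut]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    return ROCCurve(thresholds, fpr, tpr)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the pairwise statistic P(score+ > score-) + 0.5 P(tie) exactly.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pairwise_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Independent AUC oracle: fraction of correctly ordered (+,-) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateClassError("pairwise AUC needs both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


@dataclass(frozen=True)
class ClassificationReport:
    curves: tuple[ROCCurve, ...]
    fold_auc: tuple[float, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def se_auc(self) -> float:
        return self.std_auc / float(np.sqrt(len(self.fold_auc)))


def cv_classify(
    data: LabeledSamples,
    folds: int = 5,
    n_trees: int = 5000,
    seed: int = 0,
    n_jobs: int = 1,
) -> ClassificationReport:
    """Stratified k-fold CV of a random-tree ensemble, scored by ROC/AUC.

    Scores are the fraction of trees voting feasible (continuous, as needed
    for a threshold sweep); misclassification costs are equal.  Fold
    assignment and tree growth are deterministic for a fixed seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if data.n_feasible < folds or data.n_infeasible < folds:
        raise DegenerateClassError("each fold needs both classes present")
    splitter = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=substream_seed(seed, "cv-folds")
    )
    curves = []
    fold_auc = []
    for f, (train, test) in enumerate(splitter.split(data.X, data.labels)):
        y_train = data.labels[train]
        y_test = data.labels[test]
        if y_train.all() or (~y_train).all() or y_test.all() or (~y_test).all():
            raise DegenerateClassError(f"fold {f} lost a class (stratification bug)")
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=substream_seed(seed, f"forest-fold-{f}"),
            n_jobs=n_jobs,
        )
        forest.fit(data.X[train], y_train)
        pos_col = list(forest.classes_).index(True)
        scores = forest.predict_proba(data.X[test])[:, pos_col]
        curve = roc_curve(scores, y_test)
        curves.append(curve)
        fold_auc.append(auc(curve))
    return ClassificationReport(tuple(curves), tuple(fold_auc))
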