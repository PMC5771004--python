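"""Per-seed ROC curves, AUC and confusion counts.

The classifier is scored image-by-image against a reference label table.
The ROC sweeps the germinated-vote fraction m/k over its distinct values
(predict germinated when score >= threshold); the area under the curve, by
trapezoidal integration with half credit for ties, equals the probability
that a randomly chosen germinated image is ranked above a randomly chosen
un-germinated one (the Mann-Whitney rank statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FeatureMatrix, SplitSpec, labels_for, split
from .knn_classifier import DEFAULT_K, KnnModel, Prediction, knn_predict_batch


@dataclass
class ROCResult:
    """Operating points ordered by threshold descending, plus the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class = germinated."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fp_fraction(self) -> float:
        """False positives over all test images (the reporting convention)."""
        return self.fp / self.n

    @property
    def fn_fraction(self) -> float:
        return self.fn / self.n

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def roc_curve(scores, labels) -> ROCResult:
    """ROC over the distinct score values, with trapezoidal AUC.

    Raises if only one class is present (the AUC is undefined there).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels == 1)
    cum_fp = np.cumsum(sorted_labels == 0)
    # Last index of each distinct score = one operating point per threshold.
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    last = np.r_[distinct, sorted_scores.size - 1]
    thresholds = np.r_[np.inf, sorted_scores[last]]
    tpr = np.r_[0.0, cum_tp[last] / n_pos]
    fpr = np.r_[0.0, cum_fp[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def confusion(predicted, reference) -> ConfusionCounts:
    """Confusion counts of binary calls against reference labels."""
    predicted = np.asarray(predicted, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference labels differ in length")
    return ConfusionCounts(
        tp=int(((predicted == 1) & (reference == 1)).sum()),
        fp=int(((predicted == 1) & (reference == 0)).sum()),
        tn=int(((predicted == 0) & (reference == 0)).sum()),
        fn=int(((predicted == 0) & (reference == 1)).sum()),
    )


@dataclass
class RepeatResult:
    """One split/classify/evaluate run."""

    split_spec: SplitSpec
    predictions: list[Prediction]
    roc: ROCResult
    confusion: ConfusionCounts


@dataclass
class EvaluationSummary:
    """Mean and spread of AUC and error fractions over repeated splits."""

    auc_mean: float
    auc_sd: float
    fp_fraction_mean: float
    fn_fraction_mean: float
    n_repeats: int
    repeats: list[RepeatResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "fp_fraction_mean": self.fp_fraction_mean,
            "fn_fraction_mean": self.fn_fraction_mean,
            "n_repeats": self.n_repeats,
            "auc_per_repeat": [r.roc.auc for r in self.repeats],
        }


def evaluate_split(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    split_spec: SplitSpec,
    k: int = DEFAULT_K,
    rng_seed: int = 1234,
) -> RepeatResult:
    """Train on the split's train rows, score its test rows, build the ROC."""
    model = KnnModel(
        X=matrix.values[split_spec.train_idx],
        y=np.asarray(labels)[split_spec.train_idx],
        k=k,
        rng_seed=rng_seed,
    )
    test = matrix.take_rows(split_spec.test_idx)
    preds = knn_predict_batch(model, test)
    scores = np.array([p.score for p in preds])
    test_labels = np.asarray(labels)[split_spec.test_idx]
    roc = roc_curve(scores, test_labels)
    # Confusion at the k-NN majority decision itself: score >= ceil(k/2)/k.
    calls = np.array([p.label for p in preds])
    return RepeatResult(
        split_spec=split_spec,
        predictions=preds,
        roc=roc,
        confusion=confusion(calls, test_labels),
    )


def evaluate_run(
    matrix: FeatureMatrix,
    table: pd.DataFrame,
    k: int = DEFAULT_K,
    n_repeats: int = 1,
    base_seed: int = 1234,
    train_fraction: float = 0.5,
) -> EvaluationSummary:
    """Repeat random split + classify + ROC and summarise across repeats."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    labels = labels_for(matrix, table)
    repeats = []
    for i in range(n_repeats):
        seed_i = (base_seed + i) % (2**31 - 1)
        spec = split(matrix.n_images, train_fraction, seed_i)
        repeats.append(evaluate_split(matrix, labels, spec, k=k, rng_seed=seed_i))
    aucs = np.array([r.roc.auc for r in repeats])
    return EvaluationSummary(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if n_repeats > 1 else 0.0,
        fp_fraction_mean=float(np.mean([r.confusion.fp_fraction for r in repeats])),
        fn_fraction_mean=float(np.mean([r.confusion.fn_fraction for r in repeats])),
        n_repeats=n_repeats,
        repeats=repeats,
    )
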