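"""Uncertainty-driven label curation ("amended human assessment").

Human germination scores of time sequences are imperfect: a seed that
germinated and later died looks un-germinated in isolation, yet sequence
scoring marks it germinated. The curation loop re-scores the labelled set
with the k-NN classifier, surfaces the least-certain images for human
review, applies any corrections (provenance "amended"), re-applies the
monotone time propagation, and repeats until an iteration changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .dataset import FeatureMatrix, labels_for, propagate_labels
from .knn_classifier import DEFAULT_K, Prediction, self_score

Reviewer = Callable[[tuple[str, int], int], int]


@dataclass
class ReviewQueue:
    """The batch of least-certain images awaiting human review."""

    items: list[tuple[tuple[str, int], int, float]]  # (key, label, certainty)
    batch_size: int


@dataclass
class AmendmentLog:
    """Per-iteration review bookkeeping; append-only."""

    iterations: list[dict] = field(default_factory=list)
    converged: bool = False
    warning: str | None = None

    @property
    def total_changes(self) -> int:
        return sum(it["n_changed"] for it in self.iterations)

    def record(self, n_reviewed: int, changes: list[dict]) -> None:
        self.iterations.append(
            {
                "iteration": len(self.iterations) + 1,
                "n_reviewed": n_reviewed,
                "n_changed": len(changes),
                "changes": changes,
            }
        )


def build_review_queue(
    predictions: list[Prediction], batch_size: int
) -> ReviewQueue:
    """The ``batch_size`` least-certain predictions, ties ordered by key."""
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    if not predictions:
        raise ValueError("no predictions to review")
    ranked = sorted(
        predictions, key=lambda p: (p.certainty, p.image_key or ("", -1))
    )
    return ReviewQueue(
        items=[(p.image_key, p.label, p.certainty) for p in ranked[:batch_size]],
        batch_size=batch_size,
    )


def default_batch_size(n_images: int) -> int:
    """Default review batch: 1% of the images, but at least 10."""
    return max(10, n_images // 100)


def amend_until_stable(
    matrix: FeatureMatrix,
    table: pd.DataFrame,
    reviewer: Reviewer,
    k: int = DEFAULT_K,
    batch_size: int | None = None,
    max_iter: int = 20,
    mode: str = "loo",
    rng_seed: int = 1234,
) -> tuple[pd.DataFrame, AmendmentLog]:
    """Iterate score -> queue -> review -> propagate until no label changes.

    The reviewer callback receives (image key, current label) and returns
    the corrected label. Changed entries get provenance "amended" and the
    per-seed running-maximum propagation is re-applied after each iteration
    so a corrected early germination updates the later frames. Stops when an
    iteration changes zero labels, or at ``max_iter`` with a warning in the
    log (never an exception).
    """
    if batch_size is None:
        batch_size = default_batch_size(matrix.n_images)
    table = table.copy()
    log = AmendmentLog()
    for _ in range(max_iter):
        preds = self_score(
            matrix, labels_for(matrix, table), k=k, mode=mode, rng_seed=rng_seed
        )
        queue = build_review_queue(preds, batch_size)
        changes: list[dict] = []
        for key, _, _ in queue.items:
            seed_id, time_index = key
            sel = (table["seed_id"] == seed_id) & (table["time_index"] == time_index)
            current = int(table.loc[sel, "label"].iloc[0])
            new = int(reviewer(key, current))
            if new != current:
                table.loc[sel, ["label", "provenance"]] = [new, "amended"]
                changes.append(
                    {"seed_id": seed_id, "time_index": time_index,
                     "old": current, "new": new}
                )
        log.record(n_reviewed=len(queue.items), changes=changes)
        if not changes:
            log.converged = True
            return table, log
        table = propagate_labels(table)
    log.warning = f"max_iter={max_iter} reached before label stability"
    return table, log
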