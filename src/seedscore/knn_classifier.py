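"""Euclidean k-nearest-neighbour germination classifier with vote certainty.

A query image is classified by majority vote among the k training images
closest in Euclidean distance (default k = 7). Alongside the binary call
the classifier reports a certainty, max(m, k - m) / k where m is the number
of germinated neighbours: 0.5 means an even split (maximally uncertain), 1
means a unanimous vote. With 4 of 7 neighbours agreeing the certainty is
4/7 ~= 0.57. An odd k makes the vote unambiguous; for even k a tied vote is
broken at random from a seeded stream so results remain reproducible.

The continuous score m/k (germinated-vote fraction) is kept unfolded for
ROC threshold sweeps; the certainty folds it at 0.5 and cannot order the
two classes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import FeatureMatrix, SplitSpec

DEFAULT_K = 7


@dataclass
class KnnModel:
    """Training matrix, aligned binary labels, k, and the tie-break seed."""

    X: np.ndarray  # n_train x d
    y: np.ndarray  # n_train, values in {0, 1}
    k: int = DEFAULT_K
    rng_seed: int = 1234

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("training matrix must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("labels must align with training rows")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.X.shape[0] < self.k:
            raise ValueError(f"k={self.k} exceeds n_train={self.X.shape[0]}")


@dataclass
class Prediction:
    """Binary germination call with the k-NN vote bookkeeping."""

    label: int
    certainty: float  # in [0.5, 1]
    score: float  # germinated-vote fraction m/k, in [0, 1]
    neighbour_idx: np.ndarray
    image_key: tuple[str, int] | None = None


def _tie_rng(rng_seed: int, image_key: tuple[str, int] | None) -> np.random.Generator:
    # Substream keyed by image identity so batch order cannot change a
    # tie-break; falls back to the model seed for anonymous queries.
    if image_key is None:
        return np.random.default_rng(rng_seed)
    tag = zlib.crc32(f"{image_key[0]}|{image_key[1]}".encode())
    return np.random.default_rng([rng_seed, tag])


def _vote(
    model: KnnModel,
    neighbour_idx: np.ndarray,
    image_key: tuple[str, int] | None,
) -> Prediction:
    m = int(model.y[neighbour_idx].sum())
    k = model.k
    score = m / k
    if 2 * m == k:  # even-k tie, broken at random from a keyed stream
        label = int(_tie_rng(model.rng_seed, image_key).integers(2))
        certainty = 0.5
    else:
        label = int(m > k - m)
        certainty = max(m, k - m) / k
    return Prediction(
        label=label,
        certainty=certainty,
        score=score,
        neighbour_idx=neighbour_idx,
        image_key=image_key,
    )


def _neighbours(model: KnnModel, dists: np.ndarray) -> np.ndarray:
    # Stable argsort keeps the lowest training-row index on distance ties at
    # the k-th rank, so neighbour choice is deterministic.
    return np.argsort(dists, axis=-1, kind="stable")[..., : model.k]


def knn_predict(
    model: KnnModel,
    query: np.ndarray,
    image_key: tuple[str, int] | None = None,
) -> Prediction:
    """Classify one feature vector by majority vote of its k neighbours."""
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (model.X.shape[1],):
        raise ValueError(
            f"query dimension {query.shape} does not match d={model.X.shape[1]}"
        )
    d2 = ((model.X - query) ** 2).sum(axis=1)
    return _vote(model, _neighbours(model, d2), image_key)


def knn_predict_batch(
    model: KnnModel, matrix: FeatureMatrix | np.ndarray
) -> list[Prediction]:
    """Row-wise k-NN prediction; order-independent given keyed tie streams."""
    if isinstance(matrix, FeatureMatrix):
        queries = matrix.values
        keys: list[tuple[str, int] | None] = list(matrix.image_keys)
    else:
        queries = np.asarray(matrix, dtype=np.float64)
        keys = [None] * queries.shape[0]
    if queries.ndim != 2 or queries.shape[1] != model.X.shape[1]:
        raise ValueError("query matrix dimension mismatch")
    d2 = cdist(queries, model.X, metric="sqeuclidean")
    nb = _neighbours(model, d2)
    return [_vote(model, nb[i], keys[i]) for i in range(queries.shape[0])]


def self_score(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    k: int = DEFAULT_K,
    mode: str = "loo",
    split_spec: SplitSpec | None = None,
    rng_seed: int = 1234,
) -> list[Prediction]:
    """Score a labelled set against itself to surface uncertain images.

    ``loo`` scores each image against all others (itself excluded);
    ``holdout`` trains on ``split_spec.train_idx`` and scores the test rows.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = matrix.n_images
    if labels.shape != (n,):
        raise ValueError("labels must align with matrix rows")
    if mode == "loo":
        if n < k + 1:
            raise ValueError("leave-one-out needs at least k + 1 images")
        model = KnnModel(X=matrix.values, y=labels, k=k, rng_seed=rng_seed)
        d2 = cdist(matrix.values, matrix.values, metric="sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        nb = _neighbours(model, d2)
        return [_vote(model, nb[i], matrix.image_keys[i]) for i in range(n)]
    if mode == "holdout":
        if split_spec is None:
            raise ValueError("holdout mode requires a SplitSpec")
        model = KnnModel(
            X=matrix.values[split_spec.train_idx],
            y=labels[split_spec.train_idx],
            k=k,
            rng_seed=rng_seed,
        )
        return knn_predict_batch(model, matrix.take_rows(split_spec.test_idx))
    raise ValueError(f"unknown mode {mode!r}")
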