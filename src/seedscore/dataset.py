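"""Feature-matrix assembly: normalisation, PCA, label handling and splits.

Traits span several orders of magnitude (pixel counts vs ratios), so every
feature is min-max normalised to [0, 1] before any distance computation.
The 1561-dimensional space can optionally be reduced to its first principal
components (default 21). Germination labels are binary per
(seed_id, time_index); because germination is irreversible, a seed marked
germinated stays germinated for every later time point, and the pre-test
photographs (time 0) are excluded from classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .seed_imaging import ALL_FEATURE_NAMES, OBJECT_FEATURE_NAMES

LABEL_COLUMNS = ("seed_id", "time_index", "label", "provenance")


@dataclass
class FeatureMatrix:
    """n_images x n_features real matrix with feature and row identity."""

    values: np.ndarray
    feature_names: list[str]
    image_keys: list[tuple[str, int]]  # (seed_id, time_index) per row
    stage: str = "raw"  # raw | normalized | pca

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.image_keys), len(self.feature_names)):
            raise ValueError("values shape does not match keys/feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return replace(
            self,
            values=self.values[idx],
            image_keys=[self.image_keys[i] for i in np.atleast_1d(idx)],
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_names: list[str] | None = None
    ) -> "FeatureMatrix":
        """Build from a feature table with seed_id/time_index columns."""
        if feature_names is None:
            feature_names = [
                c for c in df.columns if c not in ("seed_id", "time_index")
            ]
        keys = list(zip(df["seed_id"].astype(str), df["time_index"].astype(int)))
        return cls(
            values=df[list(feature_names)].to_numpy(dtype=np.float64),
            feature_names=list(feature_names),
            image_keys=keys,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "time_index", [t for _, t in self.image_keys])
        df.insert(0, "seed_id", [s for s, _ in self.image_keys])
        return df


def object_feature_subset(matrix: FeatureMatrix) -> FeatureMatrix:
    """Restrict to the 25 object descriptors (drop histogram columns)."""
    idx = [matrix.feature_names.index(n) for n in OBJECT_FEATURE_NAMES]
    return FeatureMatrix(
        values=matrix.values[:, idx],
        feature_names=list(OBJECT_FEATURE_NAMES),
        image_keys=list(matrix.image_keys),
        stage=matrix.stage,
    )


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned from a reference (training) set."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in normalization params")


def normalize(
    matrix: FeatureMatrix, params: NormalizationParams | str = "fit"
) -> tuple[FeatureMatrix, NormalizationParams]:
    """Min-max scale every feature to [0, 1].

    With ``params="fit"`` the ranges are learned from ``matrix`` itself.
    When pre-learned params are supplied (test data), transformed values are
    clipped into [0, 1]. Constant features map to 0.
    """
    if isinstance(params, str):
        if params != "fit":
            raise ValueError("params must be NormalizationParams or 'fit'")
        params = NormalizationParams(
            feature_names=list(matrix.feature_names),
            mins=matrix.values.min(axis=0),
            maxs=matrix.values.max(axis=0),
        )
        fitted = True
    else:
        if list(params.feature_names) != list(matrix.feature_names):
            raise ValueError("feature names do not match normalization params")
        fitted = False
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (matrix.values - params.mins) / safe
    scaled[:, span == 0] = 0.0
    if not fitted:
        scaled = np.clip(scaled, 0.0, 1.0)
    return (
        FeatureMatrix(
            values=scaled,
            feature_names=list(matrix.feature_names),
            image_keys=list(matrix.image_keys),
            stage="normalized",
        ),
        params,
    )


@dataclass
class PCAModel:
    """Principal components of the (normalised) feature space.

    Loadings are eigenvectors of the covariance of the mean-centred data,
    ordered by eigenvalue descending; the sign of each component is fixed so
    its largest-magnitude loading is positive.
    """

    mean: np.ndarray
    loadings: np.ndarray  # n_features x n_components
    explained_variance: np.ndarray  # eigenvalues, descending
    explained_variance_ratio: np.ndarray
    feature_names: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                    "feature_names": self.feature_names,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            feature_names=list(d["feature_names"]),
        )


def pca_fit(matrix: FeatureMatrix, n_components: int = 21) -> PCAModel:
    """Fit a PCA on a normalised feature matrix via SVD of the centred data."""
    if matrix.stage != "normalized":
        raise ValueError("PCA expects a normalized feature matrix")
    n, d = matrix.values.shape
    if n_components > min(n, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_images, n_features)={min(n, d)}"
        )
    mean = matrix.values.mean(axis=0)
    centred = matrix.values - mean
    # SVD of the centred data gives covariance eigenvectors without forming
    # the d x d covariance (d may be 1561).
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigvals = s**2 / max(n - 1, 1)
    total = eigvals.sum()
    loadings = vt[:n_components].T
    # Sign convention: largest-|loading| entry of each component positive.
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=eigvals[:n_components],
        explained_variance_ratio=(
            eigvals[:n_components] / total if total > 0 else eigvals[:n_components]
        ),
        feature_names=list(matrix.feature_names),
    )


def pca_project(matrix: FeatureMatrix, model: PCAModel) -> FeatureMatrix:
    """Project onto the model's components: (x - mean) @ loadings."""
    if list(matrix.feature_names) != list(model.feature_names):
        raise ValueError("feature names do not match the PCA model")
    scores = (matrix.values - model.mean) @ model.loadings
    return FeatureMatrix(
        values=scores,
        feature_names=[f"PC{i + 1}" for i in range(model.n_components)],
        image_keys=list(matrix.image_keys),
        stage="pca",
    )


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------


def make_label_table(
    records: list[tuple[str, int, int]] | pd.DataFrame, provenance: str = "human"
) -> pd.DataFrame:
    """Label table: columns seed_id, time_index, label, provenance."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "provenance" not in df.columns:
            df["provenance"] = provenance
    else:
        df = pd.DataFrame(records, columns=["seed_id", "time_index", "label"])
        df["provenance"] = provenance
    df["seed_id"] = df["seed_id"].astype(str)
    df["time_index"] = df["time_index"].astype(int)
    df["label"] = df["label"].astype(int)
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels must be 0 (ungerminated) or 1 (germinated)")
    return df[list(LABEL_COLUMNS)]


def propagate_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the irreversibility of germination: per-seed running maximum.

    Once a seed is marked germinated, every later time point in its sequence
    is marked germinated too. Provenance is preserved.
    """
    if table.duplicated(subset=["seed_id", "time_index"]).any():
        raise ValueError("duplicate (seed_id, time_index) in label table")
    out = table.sort_values(["seed_id", "time_index"], kind="stable").copy()
    out["label"] = out.groupby("seed_id")["label"].cummax()
    return out.loc[table.index]


def drop_time_zero(
    matrix: FeatureMatrix, table: pd.DataFrame
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove pre-test (time 0) rows from the matrix and table consistently."""
    keep = np.array([t != 0 for _, t in matrix.image_keys])
    return matrix.take_rows(np.nonzero(keep)[0]), table[table["time_index"] != 0]


def labels_for(matrix: FeatureMatrix, table: pd.DataFrame) -> np.ndarray:
    """Label vector aligned with the matrix rows."""
    lookup = {
        (s, t): int(l)
        for s, t, l in zip(table["seed_id"], table["time_index"], table["label"])
    }
    try:
        return np.array([lookup[key] for key in matrix.image_keys], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"image key {exc.args[0]} missing from label table") from exc


@dataclass
class SplitSpec:
    """A reproducible random train/test partition of matrix rows."""

    rng_seed: int
    train_fraction: float
    train_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    test_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def split(n: int, train_fraction: float, rng_seed: int) -> SplitSpec:
    """Uniform random split; train size = round-half-up(n * train_fraction)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(rng_seed).permutation(n)
    return SplitSpec(
        rng_seed=rng_seed,
        train_fraction=train_fraction,
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
    )


def read_label_table(path: str | Path) -> pd.DataFrame:
    return make_label_table(pd.read_csv(path))


def write_label_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(LABEL_COLUMNS)].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("seed_id", "time_index") if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df


__all__ = [
    "ALL_FEATURE_NAMES",
    "FeatureMatrix",
    "NormalizationParams",
    "PCAModel",
    "SplitSpec",
    "drop_time_zero",
    "labels_for",
    "make_label_table",
    "normalize",
    "object_feature_subset",
    "pca_fit",
    "pca_project",
    "propagate_labels",
    "read_feature_table",
    "read_label_table",
    "split",
    "write_label_table",
]
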