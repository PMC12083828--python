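"""Core domain types: datasets, feature masks, optimizer configuration, run results.

A feature-selection problem is a labeled matrix of ``L`` samples by ``D``
features with ``C >= 2`` classes.  Candidate solutions are binary masks over
the ``D`` features; the optimizer works on continuous positions in
``[0, 1]^D`` and only ever sees the binary mask through the sigmoid transfer
function (see :mod:`gwofs.fitness`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io


@dataclass(frozen=True)
class Dataset:
    """A validated classification dataset.

    Attributes
    ----------
    features : ndarray of shape (L, D)
        Numeric feature matrix (expression / intensity values, unitless).
    labels : ndarray of shape (L,)
        Integer class labels remapped to ``0..C-1``.
    feature_names : tuple of str, length D
    name : str
    original_labels : ndarray of shape (L,)
        The labels as supplied, kept for reporting.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple
    name: str = "dataset"
    original_labels: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    @staticmethod
    def from_arrays(
        features,
        labels,
        feature_names: Sequence[str] | None = None,
        name: str = "dataset",
    ) -> "Dataset":
        """Build and validate a dataset from raw arrays.

        Labels are remapped to contiguous ``0..C-1`` integers (required for
        stratified folding and error counting); the original labels are kept.
        """
        features = np.asarray(features, dtype=float)
        raw_labels = np.asarray(labels).ravel()
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if features.shape[0] != raw_labels.shape[0]:
            raise ValueError(
                f"shape mismatch: {features.shape[0]} samples in the matrix "
                f"but {raw_labels.shape[0]} labels"
            )
        classes, remapped = np.unique(raw_labels, return_inverse=True)
        if feature_names is None:
            feature_names = tuple(f"f{j}" for j in range(features.shape[1]))
        ds = Dataset(
            features=features,
            labels=remapped.astype(np.int64),
            feature_names=tuple(str(n) for n in feature_names),
            name=name,
            original_labels=raw_labels,
        )
        return validate_dataset(ds)

    def to_csv(self, path) -> None:
        """Write one row per sample: feature columns then a ``label`` column."""
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        labels = self.labels if self.original_labels is None else self.original_labels
        df["label"] = labels
        df.to_csv(path, index=False, float_format="%.17g")


def validate_dataset(dataset: Dataset) -> Dataset:
    """Check all dataset invariants and return the dataset unchanged.

    Raises
    ------
    ValueError
        On missing values, shape mismatch, fewer than 2 samples or classes,
        or any class with fewer than 2 samples.
    """
    X, y = dataset.features, dataset.labels
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    L, D = X.shape
    if y.shape != (L,):
        raise ValueError(f"shape mismatch: {L} samples but {y.shape[0]} labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values: feature matrix contains NaN/inf entries")
    if L < 2:
        raise ValueError("need at least 2 samples")
    if D < 1:
        raise ValueError("need at least 1 feature")
    if len(dataset.feature_names) != D:
        raise ValueError("feature_names length does not match feature count")
    counts = np.bincount(y)
    if counts.size < 2:
        raise ValueError("need at least 2 classes")
    for c, cnt in enumerate(counts):
        if cnt < 2:
            label = c
            if dataset.original_labels is not None:
                label = np.unique(dataset.original_labels)[c]
            raise ValueError(f"class {label} has fewer than 2 samples")
    return dataset


def load_dataset(path, name: str | None = None) -> Dataset:
    """Load a dataset from CSV (feature columns + final ``label`` column) or
    from the MAT-file dialect with variables ``X`` (L x D) and ``Y`` (L x 1)
    used by the Arizona State University feature-selection repository."""
    path = Path(path)
    if name is None:
        name = path.stem
    ext = path.suffix.lower()
    if ext == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing required column 'label'")
        y = df["label"].to_numpy()
        X = df.drop(columns=["label"])
        return Dataset.from_arrays(X.to_numpy(dtype=float), y, list(X.columns), name)
    if ext == ".mat":
        mat = scipy.io.loadmat(path)
        if "X" not in mat or "Y" not in mat:
            raise ValueError(f"{path}: expected variables 'X' and 'Y'")
        return Dataset.from_arrays(mat["X"], np.asarray(mat["Y"]).ravel(), None, name)
    raise ValueError(f"unknown dataset extension {ext!r} (expected .csv or .mat)")


@dataclass(frozen=True)
class FeatureMask:
    """Binary selection vector over the D features."""

    bits: np.ndarray  # bool, shape (D,)

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def size(self) -> int:
        """Number of selected features."""
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def __eq__(self, other):
        return isinstance(other, FeatureMask) and np.array_equal(self.bits, other.bits)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for one optimization run.

    ``use_apc``/``use_afdb``/``use_adv`` toggle the three adaptive
    mechanisms: all on is AMGWO, all off is the baseline GWO, exactly one on
    gives the ablation variants APCGWO / AFDBGWO / ADVGWO.
    """

    n: int = 30  # population size
    T: int = 100  # max iterations
    seed: int | None = None
    use_apc: bool = True
    use_afdb: bool = True
    use_adv: bool = True
    knn_k: int = 5
    folds: int = 10
    scale: bool = False  # z-score features on training folds only
    scalar_mutation_noise: bool = False  # one randn per guide instead of per-dim

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("population size n must be >= 4 (three leaders + a follower)")
        if self.T < 1:
            raise ValueError("max iterations T must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def with_toggles(self, use_apc: bool, use_afdb: bool, use_adv: bool) -> "OptimizerConfig":
        return replace(self, use_apc=use_apc, use_afdb=use_afdb, use_adv=use_adv)


@dataclass
class RunResult:
    """Outcome of one optimization run."""

    best_mask: FeatureMask
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, length T
    subset_size: int
    runtime_s: float
    config: OptimizerConfig
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        cfg = {
            "n": self.config.n,
            "T": self.config.T,
            "seed": self.config.seed,
            "use_apc": self.config.use_apc,
            "use_afdb": self.config.use_afdb,
            "use_adv": self.config.use_adv,
            "knn_k": self.config.knn_k,
            "folds": self.config.folds,
            "scale": self.config.scale,
            "scalar_mutation_noise": self.config.scalar_mutation_noise,
        }
        return {
            "best_mask": self.best_mask.bits.astype(int).tolist(),
            "best_fitness": float(self.best_fitness),
            "trace": [float(v) for v in self.trace],
            "subset_size": int(self.subset_size),
            "runtime_s": float(self.runtime_s),
            "n_evaluations": int(self.n_evaluations),
            "config": cfg,
        }

    @staticmethod
    def from_dict(d: dict) -> "RunResult":
        cfg = OptimizerConfig(**d["config"])
        return RunResult(
            best_mask=FeatureMask(np.asarray(d["best_mask"], dtype=bool)),
            best_fitness=d["best_fitness"],
            trace=np.asarray(d["trace"], dtype=float),
            subset_size=d["subset_size"],
            runtime_s=d["runtime_s"],
            config=cfg,
            n_evaluations=d.get("n_evaluations", 0),
        )
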