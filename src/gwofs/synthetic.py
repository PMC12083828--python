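"""Synthetic high-dimensional, small-sample classification data.

Emulates the regime of microarray gene-expression benchmarks - hundreds to
thousands of features, tens to hundreds of samples (L << D), a handful of
classes - with a small planted subset of class-informative features amid
label-independent Gaussian noise, so feature-recovery can be scored against
a known ground truth.  Model: equal spherical covariance, class-conditional
mean shifts of ``class_sep * noise_sd`` on the informative dimensions only.
Real microarray covariance structure and batch effects are deliberately not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, FeatureMask


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    class_sep is the between-class mean shift on informative features, in
    units of noise_sd; 0 yields a dataset with no signal at all (every mask
    classifies at chance).
    """

    n_samples: int = 60
    n_features: int = 200
    n_informative: int = 10
    n_classes: int = 2
    class_sep: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.class_sep < 0:
            raise ValueError("class_sep must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples // self.n_classes < 2:
            raise ValueError("every class needs at least 2 samples")


def make_microarray(spec: SyntheticSpec):
    """Generate a dataset plus the ground-truth informative feature indices.

    Class sizes are as equal as possible (keeps stratified folding valid at
    small L).  Each informative feature carries class-conditional means
    ``sign_j * c * class_sep * noise_sd`` for class c, with a random
    per-feature sign; all other features are pure N(0, noise_sd) noise.
    The truth set is returned separately so the optimizer stays blind to it.
    """
    rng = np.random.default_rng(spec.seed)
    L, D, C = spec.n_samples, spec.n_features, spec.n_classes
    labels = np.arange(L) % C  # as-equal-as-possible class sizes
    informative = np.sort(rng.choice(D, size=spec.n_informative, replace=False))
    X = rng.normal(0.0, spec.noise_sd, size=(L, D))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    shift = spec.class_sep * spec.noise_sd
    X[:, informative] += signs * (labels[:, None] * shift)
    ds = Dataset.from_arrays(X, labels, name=f"synthetic-seed{spec.seed}")
    return ds, informative


def make_worked_fixture():
    """A tiny deterministic 20 x 6 two-class dataset with one perfect
    separator feature (column 0) and five noise columns, plus the ideal mask.

    Class 0 occupies [0.05, 0.25] and class 1 [0.75, 0.95] on feature 0, so
    a 5-NN classifier using that column alone is error-free under 10-fold
    stratified CV.
    """
    rng = np.random.default_rng(20240106)
    L = 20
    labels = np.arange(L) % 2
    sep = np.where(labels == 0, 0.0, 0.7) + np.linspace(0.05, 0.25, L)
    noise = rng.random((L, 5))
    X = np.column_stack([sep, noise])
    ds = Dataset.from_arrays(X, labels, name="worked-fixture")
    ideal = FeatureMask(np.array([1, 0, 0, 0, 0, 0], dtype=bool))
    return ds, ideal
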