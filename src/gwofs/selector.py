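"""scikit-learn estimator interface for grey-wolf wrapper feature selection."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import Dataset, OptimizerConfig
from .search import VARIANT_TOGGLES, optimize


class GreyWolfFeatureSelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selection by a grey wolf optimizer.

    A pack of ``n_wolves`` candidate solutions moves through ``[0, 1]^D``
    guided by its three best members; positions are binarized through a
    steep sigmoid into feature masks, each scored by the stratified
    cross-validated error of a K-nearest-neighbour classifier restricted to
    the selected columns.  The three adaptive mechanisms (nonlinear
    convergence schedule, fitness-distance-balance reference selection,
    neighborhood mutation) are individually toggleable; all on is AMGWO,
    all off the baseline GWO.

    Parameters
    ----------
    n_wolves : int, default=30
        Population size.
    n_iter : int, default=100
        Number of search iterations.
    use_apc, use_afdb, use_adv : bool, default=True
        Mechanism toggles (see :data:`gwofs.search.VARIANT_TOGGLES` for the
        named presets).
    n_neighbors : int, default=5
        K of the wrapped KNN classifier.
    cv : int, default=10
        Cross-validation folds for the fitness (reduced automatically when
        a class has fewer samples than folds).
    scale : bool, default=False
        Z-score features using training-fold statistics before KNN.
    random_state : int or None
        Master seed for all randomness in the run.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features_in_,)
        Best feature mask found.
    best_fitness_ : float
        Cross-validated error of the selected subset.
    trace_ : ndarray of shape (n_iter,)
        Best-so-far fitness per iteration (nonincreasing).
    run_result_ : RunResult
        Full run record (mask, trace, runtime, evaluation count, config).

    Examples
    --------
    >>> from gwofs import GreyWolfFeatureSelector
    >>> from gwofs.synthetic import SyntheticSpec, make_microarray
    >>> ds, truth = make_microarray(SyntheticSpec(seed=1))
    >>> sel = GreyWolfFeatureSelector(n_wolves=10, n_iter=10, random_state=0)
    >>> Xr = sel.fit_transform(ds.features, ds.labels)
    >>> Xr.shape[0] == ds.n_samples
    True
    """

    def __init__(
        self,
        n_wolves: int = 30,
        n_iter: int = 100,
        use_apc: bool = True,
        use_afdb: bool = True,
        use_adv: bool = True,
        n_neighbors: int = 5,
        cv: int = 10,
        scale: bool = False,
        random_state: int | None = None,
    ):
        self.n_wolves = n_wolves
        self.n_iter = n_iter
        self.use_apc = use_apc
        self.use_afdb = use_afdb
        self.use_adv = use_adv
        self.n_neighbors = n_neighbors
        self.cv = cv
        self.scale = scale
        self.random_state = random_state

    @classmethod
    def from_variant(cls, variant: str, **kwargs) -> "GreyWolfFeatureSelector":
        """Build a selector from a named preset:
        gwo | apcgwo | afdbgwo | advgwo | amgwo."""
        if variant not in VARIANT_TOGGLES:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(VARIANT_TOGGLES)}"
            )
        apc, afdb, adv = VARIANT_TOGGLES[variant]
        return cls(use_apc=apc, use_afdb=afdb, use_adv=adv, **kwargs)

    def fit(self, X, y):
        """Search for the best feature subset on (X, y)."""
        X, y = validate_data(self, X, y, dtype=float, ensure_min_samples=2)
        check_classification_targets(y)
        if self.random_state is not None and not isinstance(
            self.random_state, numbers.Integral
        ):
            raise ValueError("random_state must be an int or None")
        dataset = Dataset.from_arrays(X, y)
        config = OptimizerConfig(
            n=self.n_wolves,
            T=self.n_iter,
            seed=None if self.random_state is None else int(self.random_state),
            use_apc=self.use_apc,
            use_afdb=self.use_afdb,
            use_adv=self.use_adv,
            knn_k=self.n_neighbors,
            folds=self.cv,
            scale=self.scale,
        )
        result = optimize(dataset, config)
        self.run_result_ = result
        self.support_ = result.best_mask.bits.copy()
        self.best_fitness_ = result.best_fitness
        self.trace_ = result.trace.copy()
        self.subset_size_ = result.subset_size
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
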