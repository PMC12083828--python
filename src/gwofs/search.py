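"""The optimization loop: baseline GWO and AMGWO with toggleable mechanisms.

Per iteration t = 1..T (1-based, elitist):

1. convergence factor ``a`` from the nonlinear schedule (APC on) or the
   linear one (APC off);
2. the encircling reference for each wolf: its own position, or on odd
   iterations the highest-FDB-score individual (AFDB on);
3. guide positions from the three leaders, optionally Gaussian-mutated
   toward the best-so-far (ADV on), averaged and clipped;
4. each new position binarized once through the sigmoid transfer and the
   resulting mask scored by KNN cross-validated error on folds fixed for
   the whole run.

Exactly n fitness evaluations happen per iteration (plus n for the initial
population), so every variant runs in O(n * d * T) evaluations of the
wrapped classifier.
"""

from __future__ import annotations

import time

import numpy as np

from . import mechanisms
from .data import Dataset, OptimizerConfig, RunResult
from .engine import SwarmState, combine_guides, guide_positions, linear_a
from .fitness import binarize, cv_error, make_folds

#: Mechanism toggle presets for the named algorithm variants.
VARIANT_TOGGLES = {
    "gwo": (False, False, False),
    "apcgwo": (True, False, False),
    "afdbgwo": (False, True, False),
    "advgwo": (False, False, True),
    "amgwo": (True, True, True),
}


def _spawn_rngs(seed):
    """One master seed -> independent substreams for initialization,
    coefficients, binarization, mutation, and fold assignment."""
    ss = np.random.SeedSequence(seed)
    init_ss, coef_ss, bin_ss, mut_ss, fold_ss = ss.spawn(5)
    fold_seed = int(fold_ss.generate_state(1)[0] % (2**31))
    return (
        np.random.default_rng(init_ss),
        np.random.default_rng(coef_ss),
        np.random.default_rng(bin_ss),
        np.random.default_rng(mut_ss),
        fold_seed,
    )


def optimize(
    dataset: Dataset | None,
    config: OptimizerConfig,
    fitness_fn=None,
    n_features: int | None = None,
) -> RunResult:
    """Run the (AM)GWO loop and return the best mask found.

    ``fitness_fn(mask) -> float`` may replace the KNN-wrapper objective
    (used for testing the search dynamics against enumerable objectives);
    otherwise ``dataset`` is required and masks are scored by stratified
    cross-validated KNN error on folds fixed once per run.
    """
    t0 = time.perf_counter()
    rng_init, rng_coef, rng_bin, rng_mut, fold_seed = _spawn_rngs(config.seed)

    if fitness_fn is None:
        if dataset is None:
            raise ValueError("dataset required unless fitness_fn is given")
        fold_plan = make_folds(dataset, config.folds, fold_seed)

        def fitness_fn(mask):
            return cv_error(
                dataset,
                mask,
                knn_k=config.knn_k,
                fold_plan=fold_plan,
                scale=config.scale,
            ).fitness

        D = dataset.n_features
    else:
        D = n_features if n_features is not None else dataset.n_features

    n, T = config.n, config.T
    positions = rng_init.random((n, D))
    masks = [binarize(p, rng_bin) for p in positions]
    fits = np.array([fitness_fn(m) for m in masks], dtype=float)
    n_evals = n

    state = SwarmState(
        positions=positions,
        masks=masks,
        fitness=fits,
        alpha_pos=positions[0],
        beta_pos=positions[0],
        delta_pos=positions[0],
        alpha_fit=np.inf,
        beta_fit=np.inf,
        delta_fit=np.inf,
        best_pos=positions[0].copy(),
        best_mask=masks[0],
        best_fit=np.inf,
        t=0,
        T=T,
    )
    state.refresh_leaders()
    state.update_best()

    trace = np.empty(T)
    for t in range(1, T + 1):
        state.t = t
        a = mechanisms.nonlinear_a(t, T) if config.use_apc else linear_a(t, T)

        x_fdb = None
        if config.use_afdb and t % 2 == 1:
            table = mechanisms.fdb_scores(state.positions, state.fitness, state.best_pos)
            x_fdb = mechanisms.select_fdb_individual(table, state.positions)

        new_positions = np.empty_like(state.positions)
        for i in range(n):
            if config.use_afdb:
                ref = mechanisms.select_reference(t, state.positions[i], x_fdb)
            else:
                ref = state.positions[i]
            g = guide_positions(
                state.alpha_pos, state.beta_pos, state.delta_pos, ref, a, rng_coef
            )
            if config.use_adv:
                g = mechanisms.adaptive_mutation(
                    g, state.best_pos, rng_mut, config.scalar_mutation_noise
                )
            new_positions[i] = combine_guides(g)

        state.positions = new_positions
        state.masks = [binarize(p, rng_bin) for p in new_positions]
        state.fitness = np.array([fitness_fn(m) for m in state.masks], dtype=float)
        n_evals += n
        state.refresh_leaders()
        state.update_best()
        trace[t - 1] = state.best_fit

    return RunResult(
        best_mask=state.best_mask,
        best_fitness=state.best_fit,
        trace=trace,
        subset_size=state.best_mask.size,
        runtime_s=time.perf_counter() - t0,
        config=config,
        n_evaluations=n_evals,
    )


def run_gwo(dataset: Dataset, config: OptimizerConfig, **kw) -> RunResult:
    """Baseline GWO: all adaptive mechanisms off."""
    return optimize(dataset, config.with_toggles(False, False, False), **kw)


def run_amgwo(dataset: Dataset, config: OptimizerConfig, **kw) -> RunResult:
    """AMGWO (or an ablation variant, per the toggles already in config)."""
    return optimize(dataset, config, **kw)


def run_variant(dataset: Dataset, variant: str, config: OptimizerConfig, **kw) -> RunResult:
    """Run a named variant: gwo | apcgwo | afdbgwo | advgwo | amgwo."""
    if variant not in VARIANT_TOGGLES:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANT_TOGGLES)}")
    return optimize(dataset, config.with_toggles(*VARIANT_TOGGLES[variant]), **kw)
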