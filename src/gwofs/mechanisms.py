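"""The three adaptive mechanisms layered on the GWO chassis.

APC  - adaptive parameter control: a nonlinear convergence-factor schedule
       a(t) = 2 - 2 sin((pi/2) (t/T)^3) that stays near 2 for most of the
       run (prolonged exploration) and collapses quickly near the end.
AFDB - adaptive fitness-distance-balance reference selection: on odd
       iterations the encircling distances are measured against the
       population member with the best combined (normalized fitness +
       normalized distance-to-best) score instead of the wolf's own
       position, steering the pack toward good-but-diverse candidates.
ADV  - adaptive neighborhood mutation: each guide position is perturbed by
       Gaussian noise scaled by its offset from the best-so-far solution,
       so mutation intensity shrinks automatically as guides approach the
       incumbent optimum.

All three mechanisms compose onto the same loop; none adds a fitness
evaluation, so the per-iteration evaluation count stays at the population
size n and the overall complexity at O(n * d * T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GuideSet


def nonlinear_factor(ratio: float) -> float:
    """Nonlinear convergence factor 2 - 2 sin((pi/2) ratio^3) on ratio in [0, 1]."""
    return 2.0 - 2.0 * np.sin(np.pi / 2.0 * float(ratio) ** 3)


def nonlinear_a(t: int, T: int) -> float:
    """APC schedule evaluated at the 1-based iteration t of T (ratio t/T)."""
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} out of range 1..{T}")
    return nonlinear_factor(t / T)


@dataclass(frozen=True)
class FDBTable:
    """Fitness-distance-balance bookkeeping for a population.

    ``score = norm_f + norm_dp`` where norm_f min-max-normalizes fitness with
    the best (lowest error) mapping to 1 and norm_dp min-max-normalizes the
    Euclidean distance to the best-so-far position ascending.  A zero range
    maps the whole term to 0.
    """

    dp: np.ndarray
    norm_f: np.ndarray
    norm_dp: np.ndarray
    score: np.ndarray


def _minmax(values: np.ndarray, invert: bool) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    scaled = (values - lo) / (hi - lo)
    return 1.0 - scaled if invert else scaled


def fdb_scores(positions: np.ndarray, fitness: np.ndarray, best_pos: np.ndarray) -> FDBTable:
    """Score every candidate by normalized quality plus normalized diversity.

    ``dp_i`` is the Euclidean distance (over the D coordinates) between
    candidate i and the best-so-far position.
    """
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("FDB scoring needs a population of at least 2")
    dp = np.sqrt(np.sum((positions - best_pos) ** 2, axis=1))
    norm_f = _minmax(fitness, invert=True)  # lowest error -> 1
    norm_dp = _minmax(dp, invert=False)
    return FDBTable(dp=dp, norm_f=norm_f, norm_dp=norm_dp, score=norm_f + norm_dp)


def select_fdb_individual(table: FDBTable, positions: np.ndarray) -> np.ndarray:
    """Position of the highest-scoring candidate (ties -> lowest index)."""
    return positions[int(np.argmax(table.score))].copy()


def select_reference(t: int, own_position: np.ndarray, x_fdb: np.ndarray) -> np.ndarray:
    """Parity rule: even iterations use the wolf's own position, odd
    iterations the highest-scoring FDB individual."""
    return own_position if t % 2 == 0 else x_fdb


def adaptive_mutation(
    g: GuideSet,
    best_pos: np.ndarray,
    rng: np.random.Generator,
    scalar_noise: bool = False,
) -> GuideSet:
    """Perturb each guide toward/around the best-so-far solution.

    offset_k = best - X_k;  X_k <- X_k + offset_k * randn, with standard
    normal draws per dimension (or one scalar draw per guide when
    ``scalar_noise``).  A guide already at the best is left unchanged;
    the perturbation is mean-zero, so guides are unbiased.  Mutated guides
    are not re-clipped here - clipping happens once after combination.
    """
    D = best_pos.shape[0]
    mutated = []
    for xk in (g.x1, g.x2, g.x3):
        noise = rng.standard_normal() if scalar_noise else rng.standard_normal(D)
        mutated.append(xk + (best_pos - xk) * noise)
    return GuideSet(
        d_alpha=g.d_alpha,
        d_beta=g.d_beta,
        d_delta=g.d_delta,
        x1=mutated[0],
        x2=mutated[1],
        x3=mutated[2],
    )
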