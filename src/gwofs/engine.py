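"""Baseline grey wolf optimizer primitives.

The pack's three best candidates (alpha, beta, delta) guide every wolf's
move.  For one wolf with reference position ``ref`` (its own position in the
baseline) and convergence factor ``a``:

    D_l = | C_l * X_l - ref |          for each leader l in {alpha, beta, delta}
    X_l' = X_l - A_l * D_l
    X(t+1) = (X_a' + X_b' + X_d') / 3, clipped to [0, 1]^D

with per-dimension coefficients A = 2 a r1 - a (in [-a, a]) and C = 2 r2
(in [0, 2]), r1, r2 ~ U(0,1) drawn independently for each leader.  The
factor ``a`` decays linearly from 2 to 0 over the run, trading exploration
for exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CoefficientSet:
    """Per-dimension GWO step coefficients for one leader."""

    a: float
    r1: np.ndarray
    r2: np.ndarray
    A: np.ndarray  # 2 a r1 - a, componentwise in [-a, a]
    C: np.ndarray  # 2 r2, componentwise in [0, 2]


@dataclass(frozen=True)
class GuideSet:
    """Leader distances and the three guide positions for one wolf."""

    d_alpha: np.ndarray
    d_beta: np.ndarray
    d_delta: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray


@dataclass
class SwarmState:
    """Population snapshot: positions, masks, fitnesses, leaders, best-so-far."""

    positions: np.ndarray  # (n, D)
    masks: list  # n FeatureMask
    fitness: np.ndarray  # (n,)
    alpha_pos: np.ndarray
    beta_pos: np.ndarray
    delta_pos: np.ndarray
    alpha_fit: float
    beta_fit: float
    delta_fit: float
    best_pos: np.ndarray
    best_mask: object
    best_fit: float
    t: int  # current iteration, 1-based
    T: int

    def _ranking(self) -> np.ndarray:
        """Ascending fitness; equal-error candidates rank by smaller subset
        (the wrapper-FS convention: at equal error prefer fewer features),
        then by agent index for determinism."""
        sizes = np.array([m.size for m in self.masks])
        return np.lexsort((np.arange(len(self.masks)), sizes, self.fitness))

    def refresh_leaders(self) -> None:
        """alpha/beta/delta = the three best of the current population."""
        order = self._ranking()
        ia, ib, id_ = order[0], order[1], order[2]
        self.alpha_pos = self.positions[ia].copy()
        self.beta_pos = self.positions[ib].copy()
        self.delta_pos = self.positions[id_].copy()
        self.alpha_fit = float(self.fitness[ia])
        self.beta_fit = float(self.fitness[ib])
        self.delta_fit = float(self.fitness[id_])

    def update_best(self) -> None:
        """Elitist best-so-far: replaced on strictly lower error, or on a
        strictly smaller subset at equal error.  Fitness never worsens."""
        i = int(self._ranking()[0])
        f, m = float(self.fitness[i]), self.masks[i]
        if f < self.best_fit or (f == self.best_fit and m.size < self.best_mask.size):
            self.best_pos = self.positions[i].copy()
            self.best_mask = m
            self.best_fit = f


def linear_a(t: int, T: int) -> float:
    """Linear convergence factor: 2 at t=1 decaying to 0 at t=T.

    Uses a = 2 (1 - (t-1)/(T-1)); T = 1 degenerates to a = 2.
    """
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} out of range 1..{T}")
    if T == 1:
        return 2.0
    return 2.0 * (1.0 - (t - 1) / (T - 1))


def draw_coefficients(a: float, D: int, rng: np.random.Generator) -> CoefficientSet:
    """Draw per-dimension A = 2 a r1 - a and C = 2 r2 for one leader."""
    r1 = rng.random(D)
    r2 = rng.random(D)
    return CoefficientSet(a=a, r1=r1, r2=r2, A=2.0 * a * r1 - a, C=2.0 * r2)


def guide_positions(
    alpha_pos: np.ndarray,
    beta_pos: np.ndarray,
    delta_pos: np.ndarray,
    reference: np.ndarray,
    a: float,
    rng: np.random.Generator,
    coefficients: tuple | None = None,
) -> GuideSet:
    """Hunting step for one wolf: distances to the three leaders and the
    three guide positions.

    ``reference`` is the wolf's own position in the baseline; under the
    fitness-distance-balance mechanism it may be the highest-scoring FDB
    individual instead.  ``coefficients`` may supply explicit
    ``CoefficientSet`` triples (used by tests to force draws).
    """
    D = reference.shape[0]
    if coefficients is None:
        coefficients = tuple(draw_coefficients(a, D, rng) for _ in range(3))
    ca, cb, cd = coefficients
    d_alpha = np.abs(ca.C * alpha_pos - reference)
    d_beta = np.abs(cb.C * beta_pos - reference)
    d_delta = np.abs(cd.C * delta_pos - reference)
    return GuideSet(
        d_alpha=d_alpha,
        d_beta=d_beta,
        d_delta=d_delta,
        x1=alpha_pos - ca.A * d_alpha,
        x2=beta_pos - cb.A * d_beta,
        x3=delta_pos - cd.A * d_delta,
    )


def combine_guides(g: GuideSet) -> np.ndarray:
    """New position = mean of the three guides, clipped to [0, 1]^D."""
    return np.clip((g.x1 + g.x2 + g.x3) / 3.0, 0.0, 1.0)
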