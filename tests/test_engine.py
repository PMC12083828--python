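"""Baseline GWO primitives and search-loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwofs.data import FeatureMask, OptimizerConfig
from gwofs.engine import (
    CoefficientSet,
    combine_guides,
    draw_coefficients,
    guide_positions,
    linear_a,
)
from gwofs.search import optimize, run_gwo


class _OnesRng:
    """Fake generator whose uniform draws are all ones (forces endpoints)."""

    def random(self, n):
        return np.ones(n)


class _ZerosRng:
    def random(self, n):
        return np.zeros(n)


def _unit_coeffs(a, D):
    """Coefficients forced to C=1, A=0 (r2=0.5, r1 such that A=0)."""
    one = np.full(D, 0.5)
    return CoefficientSet(a=a, r1=one, r2=one, A=np.zeros(D), C=np.ones(D))


class TestLinearSchedule:
    def test_starts_at_two(self):
        assert linear_a(1, 100) == 2.0

    def test_ends_at_zero(self):
        assert linear_a(100, 100) == 0.0

    def test_midpoint_of_odd_ramp(self):
        T = 101
        assert linear_a((T + 1) // 2, T) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        vals = [linear_a(t, 50) for t in range(1, 51)]
        assert np.all(np.diff(vals) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            linear_a(0, 10)
        with pytest.raises(ValueError):
            linear_a(11, 10)

    def test_single_iteration_degenerates_to_two(self):
        assert linear_a(1, 1) == 2.0


class TestCoefficients:
    def test_zero_a_gives_zero_A(self):
        c = draw_coefficients(0.0, 8, np.random.default_rng(0))
        assert np.array_equal(c.A, np.zeros(8))

    def test_forced_endpoints(self):
        up = draw_coefficients(2.0, 3, _OnesRng())
        assert np.allclose(up.A, 2.0) and np.allclose(up.C, 2.0)
        dn = draw_coefficients(2.0, 3, _ZerosRng())
        assert np.allclose(dn.A, -2.0) and np.allclose(dn.C, 0.0)

    def test_empirical_ranges(self):
        rng = np.random.default_rng(1)
        for a in (0.3, 1.0, 2.0):
            c = draw_coefficients(a, 10_000, rng)
            assert np.all((c.A >= -a) & (c.A <= a))
            assert np.all((c.C >= 0.0) & (c.C <= 2.0))


class TestGuides:
    def test_zero_step_returns_leaders(self):
        rng = np.random.default_rng(0)
        D = 4
        alpha, beta, delta = rng.random(D), rng.random(D), rng.random(D)
        ref = rng.random(D)
        coeffs = tuple(_unit_coeffs(0.0, D) for _ in range(3))
        g = guide_positions(alpha, beta, delta, ref, 0.0, rng, coefficients=coeffs)
        assert np.array_equal(g.x1, alpha)
        assert np.array_equal(g.x2, beta)
        assert np.array_equal(g.x3, delta)

    def test_reference_at_alpha_gives_zero_distance(self):
        rng = np.random.default_rng(1)
        D = 3
        alpha = rng.random(D)
        coeffs = tuple(_unit_coeffs(1.0, D) for _ in range(3))
        g = guide_positions(alpha, rng.random(D), rng.random(D), alpha, 1.0, rng,
                            coefficients=coeffs)
        assert np.allclose(g.d_alpha, 0.0)

    def test_matches_literal_transcription(self):
        """Brute-force re-evaluation of the encircling equations with the
        same coefficient draws."""
        rng = np.random.default_rng(2)
        D = 3
        for _ in range(20):
            a = float(rng.random() * 2)
            alpha, beta, delta = rng.random(D), rng.random(D), rng.random(D)
            ref = rng.random(D)
            coeffs = tuple(draw_coefficients(a, D, rng) for _ in range(3))
            g = guide_positions(alpha, beta, delta, ref, a, rng, coefficients=coeffs)
            ca, cb, cd = coeffs
            for j in range(D):
                d_a = abs(ca.C[j] * alpha[j] - ref[j])
                d_b = abs(cb.C[j] * beta[j] - ref[j])
                d_d = abs(cd.C[j] * delta[j] - ref[j])
                assert g.x1[j] == pytest.approx(alpha[j] - ca.A[j] * d_a, abs=1e-12)
                assert g.x2[j] == pytest.approx(beta[j] - cb.A[j] * d_b, abs=1e-12)
                assert g.x3[j] == pytest.approx(delta[j] - cd.A[j] * d_d, abs=1e-12)

    def test_combine_is_clipped_mean(self):
        from gwofs.engine import GuideSet

        v = np.array([0.2, 0.8])
        g = GuideSet(*([np.zeros(2)] * 3), x1=v, x2=v, x3=v)
        assert np.allclose(combine_guides(g), v, atol=1e-15)
        g2 = GuideSet(*([np.zeros(2)] * 3),
                      x1=np.array([0.0, 0.0]),
                      x2=np.array([3.0, 0.0]),
                      x3=np.array([0.0, 3.0]))
        assert np.array_equal(combine_guides(g2), np.array([1.0, 1.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_combined_position_in_unit_box(self, seed):
        rng = np.random.default_rng(seed)
        from gwofs.engine import GuideSet

        g = GuideSet(*([np.zeros(3)] * 3),
                     x1=rng.normal(scale=5, size=3),
                     x2=rng.normal(scale=5, size=3),
                     x3=rng.normal(scale=5, size=3))
        out = combine_guides(g)
        assert np.all((out >= 0.0) & (out <= 1.0))


def _table_fitness(table):
    def fn(mask):
        return table[tuple(mask.bits.astype(int))]

    return fn


class TestSearchLoop:
    def test_trace_nonincreasing_and_final_matches_best(self, worked_fixture):
        ds, _ = worked_fixture
        res = run_gwo(ds, OptimizerConfig(n=8, T=15, seed=0))
        assert np.all(np.diff(res.trace) <= 0)
        assert res.trace[-1] == res.best_fitness
        assert res.subset_size == res.best_mask.size

    def test_single_iteration_contract(self, worked_fixture):
        ds, _ = worked_fixture
        res = run_gwo(ds, OptimizerConfig(n=6, T=1, seed=1))
        assert res.trace.shape == (1,)
        assert res.trace[0] == res.best_fitness

    def test_deterministic_under_seed(self, worked_fixture):
        ds, _ = worked_fixture
        cfg = OptimizerConfig(n=6, T=10, seed=12)
        a = run_gwo(ds, cfg)
        b = run_gwo(ds, cfg)
        assert a.best_mask == b.best_mask
        assert np.array_equal(a.trace, b.trace)

    def test_evaluation_count_is_n_per_iteration(self, worked_fixture):
        ds, _ = worked_fixture
        counter = {"calls": 0}
        from gwofs.fitness import cv_error as real_cv

        def counting_fitness(mask):
            counter["calls"] += 1
            return real_cv(ds, mask, fold_seed=0).fitness

        n, T = 7, 9
        res = optimize(ds, OptimizerConfig(n=n, T=T, seed=0,
                                           use_apc=False, use_afdb=False,
                                           use_adv=False),
                       fitness_fn=counting_fitness)
        assert counter["calls"] == n * (T + 1)  # initial population + T sweeps
        assert res.n_evaluations == n * (T + 1)

    def test_enumeration_bounds_final_best(self):
        """Against a frozen mask->fitness table on D=4, the search never beats
        the global minimum and usually attains it."""
        rng = np.random.default_rng(99)
        table = {}
        import itertools

        for bits in itertools.product([0, 1], repeat=4):
            table[bits] = float(rng.random()) if any(bits) else 1.0
        gmin = min(v for k, v in table.items() if any(k))
        hits = 0
        for seed in range(10):
            res = optimize(None, OptimizerConfig(n=8, T=40, seed=seed,
                                                 use_apc=False, use_afdb=False,
                                                 use_adv=False),
                           fitness_fn=_table_fitness(table), n_features=4)
            assert res.best_fitness >= gmin - 1e-12
            hits += res.best_fitness == pytest.approx(gmin, abs=1e-12)
        assert hits >= 9
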