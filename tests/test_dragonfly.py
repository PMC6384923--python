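"""Swarm dynamics: factor schedules, strategy terms, binary transition, run loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdaselect import (
    BDAConfig,
    FitnessConfig,
    binary_update,
    levy_flight,
    rmsecv,
    run_bda,
    schedule_factors,
    step_update,
    transfer,
)
from bdaselect.dragonfly import (
    SwarmFactors,
    alignment,
    cohesion,
    enemy_distraction,
    food_attraction,
    levy_sigma,
    separation,
)


class TestFactorSchedule:
    def test_initial_iteration_endpoints(self, rng):
        f = schedule_factors(0, 50, rng)
        assert f.w == pytest.approx(0.9)
        assert f.theta == pytest.approx(0.1)
        assert f.e == pytest.approx(0.1)

    def test_final_iteration_endpoints(self, rng):
        f = schedule_factors(50, 50, rng)
        assert f.w == pytest.approx(0.4)
        assert f.s == f.a == f.c == f.e == 0.0

    def test_midpoint_theta_hits_zero(self, rng):
        assert schedule_factors(25, 50, rng).theta == pytest.approx(0.0)

    def test_out_of_range_iteration_rejected(self, rng):
        with pytest.raises(ValueError):
            schedule_factors(51, 50, rng)
        with pytest.raises(ValueError):
            schedule_factors(-1, 50, rng)

    def test_bounds_hold_on_grid_sweep(self, rng):
        """w in [0.4,0.9]; s,a,c in [0,0.2]; f in [0,2]; e in [0,0.1];
        s=a=c=e=0 in the second half of every run."""
        for max_iter in (2, 7, 10, 50, 100):
            for it in range(max_iter + 1):
                f = schedule_factors(it, max_iter, rng)
                assert 0.4 - 1e-12 <= f.w <= 0.9 + 1e-12
                for x in (f.s, f.a, f.c):
                    assert 0.0 <= x <= 0.2 + 1e-12
                assert 0.0 <= f.f <= 2.0
                assert 0.0 <= f.e <= 0.1 + 1e-12
                if it > max_iter / 2:
                    assert f.s == f.a == f.c == f.e == 0.0


class TestStrategyTerms:
    def test_separation_hand_case(self):
        np.testing.assert_allclose(
            separation([0, 0], [[1, 0], [0, 1]]), [1.0, 1.0]
        )

    def test_separation_coincident_and_empty(self):
        np.testing.assert_allclose(separation([1, 1], [[1, 1], [1, 1]]), [0, 0])
        np.testing.assert_allclose(separation([1, 1], np.empty((0, 2))), [0, 0])

    def test_alignment_mean_and_conventions(self):
        np.testing.assert_allclose(alignment([[2, 0], [0, 2]]), [1, 1])
        np.testing.assert_allclose(alignment([[3, -1]]), [3, -1])
        np.testing.assert_allclose(alignment(np.empty((0, 2))), [0, 0])

    def test_cohesion_centroid_cases(self):
        np.testing.assert_allclose(cohesion([1, 1], [[1, 1]]), [0, 0])
        np.testing.assert_allclose(cohesion([0, 0], [[2, 0], [0, 2]]), [1, 1])
        np.testing.assert_allclose(cohesion([5, 5], np.empty((0, 2))), [0, 0])

    def test_food_and_enemy_terms(self):
        np.testing.assert_allclose(food_attraction([1, 0], [0, 1]), [-1, 1])
        np.testing.assert_allclose(food_attraction([1, 1], [1, 1]), [0, 0])
        # the enemy term enters as a sum, exactly as the model prints it
        np.testing.assert_allclose(enemy_distraction([0, 1], [1, 0]), [1, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            separation([0, 0], [[1, 0, 0]])
        with pytest.raises(ValueError):
            food_attraction([0, 0], [1, 0, 0])


class TestStepUpdate:
    def test_identity_when_only_inertia(self):
        factors = SwarmFactors(w=1.0, s=0, a=0, c=0, f=0, e=0, theta=0)
        prev = np.array([1.0, -2.0])
        zero = np.zeros(2)
        np.testing.assert_allclose(
            step_update(prev, zero, zero, zero, zero, zero, factors, 6.0), prev
        )

    def test_single_food_term(self):
        factors = SwarmFactors(w=0.0, s=0, a=0, c=0, f=1.0, e=0, theta=0)
        zero = np.zeros(2)
        np.testing.assert_allclose(
            step_update(zero, zero, zero, zero, np.array([1.0, -1.0]), zero,
                        factors, 6.0),
            [1.0, -1.0],
        )

    def test_matches_direct_formula_on_random_instances(self, rng):
        for _ in range(20):
            vecs = rng.normal(size=(6, 5))
            w, s, a, c, f, e = rng.uniform(0, 1, size=6)
            factors = SwarmFactors(w=w, s=s, a=a, c=c, f=f, e=e, theta=0.0)
            expected = np.clip(
                s * vecs[1] + a * vecs[2] + c * vecs[3] + f * vecs[4]
                + e * vecs[5] + w * vecs[0],
                -2.5, 2.5,
            )
            got = step_update(*vecs, factors, 2.5)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_non_finite_rejected(self):
        factors = SwarmFactors(w=1, s=0, a=0, c=0, f=0, e=0, theta=0)
        bad = np.array([np.inf, 0.0])
        zero = np.zeros(2)
        with pytest.raises(ValueError):
            step_update(bad, zero, zero, zero, zero, zero, factors, 6.0)


class TestLevyFlight:
    def test_sigma_matches_symbolic_formula(self):
        beta = 1.5
        num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
        den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
        assert levy_sigma(beta) == pytest.approx((num / den) ** (1 / beta), rel=1e-12)

    def test_linear_in_prefactor(self):
        a = levy_flight(100, 1.5, np.random.default_rng(3), prefactor=0.10)
        b = levy_flight(100, 1.5, np.random.default_rng(3), prefactor=0.20)
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_seeded_determinism(self):
        a = levy_flight(10, 1.5, np.random.default_rng(9))
        b = levy_flight(10, 1.5, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            levy_flight(5, 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            levy_flight(5, 2.5, np.random.default_rng(0))


class TestTransfer:
    def test_closed_form_values(self):
        assert transfer(0.0) == 0.0
        assert transfer(1.0) == pytest.approx(1 / math.sqrt(2))

    @given(st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_and_symmetry(self, dx):
        t = transfer(dx)
        assert 0.0 <= t < 1.0
        assert t == pytest.approx(transfer(-dx), abs=1e-15)

    def test_monotone_in_magnitude_and_limit(self):
        xs = np.linspace(0, 500, 10001)
        ts = transfer(xs)
        assert np.all(np.diff(ts) > 0)
        assert ts[-1] > 0.99999

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            transfer(np.inf)


class TestBinaryUpdate:
    def test_zero_step_never_flips(self, rng):
        bits = (rng.random(100) < 0.5).astype(np.int8)
        out = binary_update(bits, np.zeros(100), rng.random(100))
        np.testing.assert_array_equal(out, bits)

    def test_threshold_behavior(self):
        assert binary_update(1, 1.0, 0.99) == 1  # T(1)~0.707 < 0.99
        assert binary_update(1, 1.0, 0.1) == 0  # flips: complement of 1
        assert binary_update(0, -1.0, 0.1) == 1

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binary_update(1, 1.0, 1.5)

    @pytest.mark.parametrize("dx", [0.25, 1.0, 3.0])
    def test_flip_rate_matches_transfer_probability(self, dx):
        """Monte-Carlo flip frequency ~ Bernoulli(T(dx)) within 3 SEs."""
        n = 20000
        rng = np.random.default_rng(hash(dx) % 2**31)
        flips = binary_update(np.ones(n, dtype=np.int8), np.full(n, dx),
                              rng.random(n))
        rate = np.mean(flips == 0)
        p = transfer(dx)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se


class TestRunLoop:
    def _tiny(self):
        from bdaselect import SyntheticSpec, generate

        spec = SyntheticSpec(
            n_samples=20,
            grid=(900.0, 1100.0, 2.0),
            n_components=2,
            band_centers_nm=(950.0, 1050.0),
            band_widths_nm=(20.0, 25.0),
            informative_components=(0,),
            coefficients=(1.0,),
            noise_sd_absorbance=0.0,
            noise_sd_target=0.0,
            seed=5,
        )
        return generate(spec)

    def test_minimal_run_returns_evaluated_individual(self):
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=0)
        result = run_bda(ds, config, BDAConfig(max_iter=1, n_dragonflies=1, seed=4))
        assert result.trace.shape == (1,)
        assert result.best_cost == rmsecv(ds, result.best_mask, config).rmsecv

    def test_seeded_determinism(self):
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=1)
        cfg = BDAConfig(max_iter=10, n_dragonflies=5, seed=77)
        r1 = run_bda(ds, config, cfg)
        r2 = run_bda(ds, config, cfg)
        np.testing.assert_array_equal(r1.best_mask.bits, r2.best_mask.bits)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_trace_non_increasing(self):
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=2)
        result = run_bda(ds, config, BDAConfig(max_iter=20, n_dragonflies=5, seed=3))
        assert np.all(np.diff(result.trace) <= 1e-15)

    def test_never_worse_than_all_channels_reference(self):
        """The optimizer's final mask must beat its trivial feasible reference."""
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=3)
        result = run_bda(ds, config, BDAConfig(max_iter=50, n_dragonflies=10, seed=6))
        all_on = rmsecv(ds, np.ones(ds.n_channels, dtype=np.int8), config).rmsecv
        assert result.best_cost <= all_on + 1e-12

    def test_stop_tolerance_can_end_early(self):
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=4)
        cfg = BDAConfig(max_iter=50, n_dragonflies=5, seed=1, stop_tol=1e-3)
        result = run_bda(ds, config, cfg)
        assert result.n_iterations <= 50
        assert result.trace.size == result.n_iterations

    def test_channel_count_mismatch_rejected(self):
        ds, _ = self._tiny()
        config = FitnessConfig.for_dataset(ds, rng=0)
        with pytest.raises(ValueError, match="channels"):
            run_bda(ds, config, BDAConfig(n_channels=9, seed=0))
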