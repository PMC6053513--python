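"""Bootstrap significance test, its enumeration oracle, and the machine-noise screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import matlith as ml


def trip(*values, **kw):
    return ml.TriplicateSet(values, **kw)


class TestDeltaAvg:
    def test_difference_of_means(self):
        assert ml.delta_avg(trip(1, 2, 3), trip(0, 0, 0)) == pytest.approx(2.0)

    def test_identity_and_antisymmetry(self):
        a, b = trip(1.5, 2.5, 3.5), trip(0.5, 1.0, 2.0)
        assert ml.delta_avg(a, a) == 0.0
        assert ml.delta_avg(a, b) == pytest.approx(-ml.delta_avg(b, a))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ml.TriplicateSet([])


class TestExactEnumeration:
    def test_fully_separated_pool_is_one_in_64(self):
        # Delta_res >= 10 requires all three A-draws = 10 and all three
        # B-draws = 0: (1/2)^3 * (1/2)^3 = 1/64.
        p = ml.exact_null_p(trip(10, 10, 10), trip(0, 0, 0))
        assert p == pytest.approx(1 / 64, abs=0)

    def test_degenerate_constant_pool(self):
        p = ml.exact_null_p(trip(5, 5, 5), trip(5, 5, 5))
        assert p == 1.0

    def test_zero_observed_difference_is_not_significant(self):
        # Delta_exp = 0 and the null is symmetric, so at least half the
        # enumeration mass lies at or above it.
        p = ml.exact_null_p(trip(1, 2, 3), trip(1, 2, 3))
        assert p >= 0.5

    def test_two_plus_three_pool(self):
        p = ml.exact_null_p(trip(10, 10), trip(0, 0, 0))
        # all two A-draws 10 (2/5)^2 and all three B-draws 0 (3/5)^3
        assert p == pytest.approx((2 / 5) ** 2 * (3 / 5) ** 3, abs=1e-12)

    def test_pool_too_large_rejected(self):
        with pytest.raises(ValueError):
            ml.exact_null_p(
                ml.TriplicateSet([1] * 5), ml.TriplicateSet([2] * 5)
            )


class TestBootstrap:
    def test_matches_enumeration_on_separated_pool(self):
        res = ml.bootstrap_p(trip(10, 10, 10), trip(0, 0, 0), 20000, seed=3)
        p_exact = 1 / 64
        sd = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(res.p_value - p_exact) <= 3 * sd

    @pytest.mark.parametrize("seed", [0, 11, 29])
    def test_converges_to_enumeration_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        a = trip(*rng.normal(0.3, 1, 3))
        b = trip(*rng.normal(0.0, 1, 3))
        p_exact = ml.exact_null_p(a, b)
        res = ml.bootstrap_p(a, b, 20000, seed=seed + 1000)
        sd = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(res.p_value - p_exact) <= 3 * sd + 1e-12

    def test_degenerate_pool_gives_p_one(self):
        res = ml.bootstrap_p(trip(2, 2, 2), trip(2, 2, 2), 500, seed=0)
        assert res.delta_avg_exp == 0.0
        assert np.all(res.null_distribution == 0.0)
        assert res.p_value == 1.0

    def test_seeded_runs_are_bit_reproducible(self):
        a, b = trip(1.1, 2.2, 3.3), trip(0.5, 0.7, 0.2)
        r1 = ml.bootstrap_p(a, b, 1000, seed=5)
        r2 = ml.bootstrap_p(a, b, 1000, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_distribution, r2.null_distribution)

    def test_add_one_estimator_never_zero(self):
        res = ml.bootstrap_p(
            trip(100, 101, 102), trip(0, 1, 2), 200, seed=0, estimator="add-one"
        )
        assert res.p_value >= 1 / 201

    def test_two_sided_at_least_one_sided(self):
        a, b = trip(1.0, 1.2, 1.4), trip(0.0, 0.3, 0.1)
        one = ml.bootstrap_p(a, b, 4000, seed=2).p_value
        two = ml.bootstrap_p(a, b, 4000, seed=2, alternative="two-sided").p_value
        assert two >= one

    def test_resample_sizes_mirror_originals(self):
        res = ml.bootstrap_p(trip(1, 2), trip(3, 4, 5), 100, seed=0)
        assert res.n_resamples == 100
        assert len(res.null_distribution) == 100

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ml.bootstrap_p(trip(1, 2, 3), trip(4, 5, 6), 0)
        with pytest.raises(ValueError):
            ml.bootstrap_p(ml.TriplicateSet([1.0]), trip(1, 2, 3), 10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, derandomize=True)
    def test_p_value_always_a_probability(self, seed):
        rng = np.random.default_rng(seed)
        a = trip(*rng.normal(size=3))
        b = trip(*rng.normal(size=3))
        res = ml.bootstrap_p(a, b, 200, seed=seed)
        assert 0.0 <= res.p_value <= 1.0


class TestNullCalibration:
    def test_size_near_nominal_under_true_null(self):
        # modest n here; the full 2000-pair check runs with the acceptance suite
        frac = ml.stats.null_calibration(n_pairs=400, n_resamples=500, seed=10)
        assert 0.02 <= frac <= 0.12


class TestMachineNoise:
    def test_triplicate_mean_and_difference_sigmas(self):
        mv = ml.propagate_machine_sigma(0.1, 3, 3)
        assert mv.sigma_mean == pytest.approx(0.058, abs=5e-4)
        assert mv.sigma_diff == pytest.approx(0.082, abs=5e-4)

    def test_single_measurement_identity(self):
        mv = ml.propagate_machine_sigma(0.1, 1, 1)
        assert mv.sigma_mean_a == pytest.approx(0.1)
        assert mv.sigma_diff == pytest.approx(0.1 * np.sqrt(2))

    def test_quadrature_for_unequal_groups(self):
        mv = ml.propagate_machine_sigma(0.1, 2, 3)
        assert mv.sigma_diff == pytest.approx(
            np.sqrt(0.01 / 2 + 0.01 / 3), rel=1e-12
        )

    @pytest.mark.parametrize(
        "z, sided, expected",
        [
            (2.0, "two", 0.0455),   # the 5 % screen at 2 sigma
            (0.0, "two", 1.0),
            (1.0, "one", 0.1587),
        ],
    )
    def test_normal_tail_probabilities(self, z, sided, expected):
        p = ml.machine_variability_prob(z * 0.082, 0.082, sided=sided)
        assert p == pytest.approx(expected, abs=5e-4)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ml.propagate_machine_sigma(0.0)
        with pytest.raises(ValueError):
            ml.machine_variability_prob(0.1, 0.0)
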