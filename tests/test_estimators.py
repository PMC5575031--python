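"""Unit and property tests for the concentration estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import poissonplus as pp
from poissonplus.estimators import SIGMA_SWITCH


def truncnorm_poisson_zero_oracle(c, v0, sigma):
    """P(neg) by adaptive quadrature of the truncated-normal mixture.

    Independent of the erfc closed form used by the implementation: the
    zero-occupancy probability exp(-c v) is averaged over the truncated
    normal density by numerical integration.
    """
    kernel = lambda v: math.exp(-((v - v0) ** 2) / (2.0 * sigma * sigma))
    hi = v0 + 12.0 * sigma
    norm = quad(kernel, 0.0, hi)[0]
    num = quad(lambda v: math.exp(-c * v) * kernel(v), 0.0, hi, limit=200)[0]
    return num / norm


class TestPartitionCounts:
    def test_observed_fraction(self):
        assert pp.observed_p_negative(pp.PartitionCounts(20000, 20000)) == 1.0
        assert pp.observed_p_negative(pp.PartitionCounts(20000, 0)) == 0.0
        assert pp.observed_p_negative(pp.PartitionCounts(4, 1)) == 0.25

    @pytest.mark.parametrize(
        "n_total,n_negative", [(0, 0), (10, -1), (10, 11), (-5, 0)]
    )
    def test_invalid_counts_rejected(self, n_total, n_negative):
        with pytest.raises(pp.InvalidInputError):
            pp.PartitionCounts(n_total, n_negative)


class TestVolumeModel:
    def test_invariants(self):
        with pytest.raises(pp.InvalidInputError):
            pp.VolumeModel(0.0, 1.0)
        with pytest.raises(pp.InvalidInputError):
            pp.VolumeModel(1.0, -0.1)
        assert pp.VolumeModel(755.0, 75.5).cv == pytest.approx(0.1)

    def test_high_cv_flagged_not_fatal(self):
        assert pp.VolumeModel(1.0, 0.6).cv_exceeds_threshold
        assert not pp.VolumeModel(1.0, 0.3).cv_exceeds_threshold


class TestPoisson:
    def test_zero_concentration_at_all_negative(self):
        est = pp.estimate_poisson(1.0, 755.0)
        assert est.c_per_volume == 0.0
        assert est.copies_per_microliter == 0.0

    def test_identity_at_e_minus_one(self):
        assert pp.estimate_poisson(math.exp(-1.0), 1.0).c_per_volume == pytest.approx(
            1.0, rel=1e-12
        )

    def test_half_negative_at_755pl(self):
        # ln(2)/755 pL^-1 -> 918.0757 copies/uL
        est = pp.estimate_poisson(0.5, 755.0)
        assert est.copies_per_microliter == pytest.approx(918.0757358409871, rel=1e-12)

    def test_saturated_and_invalid(self):
        with pytest.raises(pp.SaturatedChipError):
            pp.estimate_poisson(0.0, 755.0)
        for bad in (-0.1, 1.5, float("nan")):
            with pytest.raises(pp.InvalidInputError):
                pp.estimate_poisson(bad, 755.0)


class TestValidityLimit:
    @pytest.mark.parametrize(
        "v0,sigma,expected",
        [
            (1.0, 0.5, math.exp(-2.0)),
            (1.0, 0.1, math.exp(-50.0)),
            (755.0, 0.0, 0.0),
        ],
    )
    def test_limit_values(self, v0, sigma, expected):
        assert pp.validity_limit_p_neg(pp.VolumeModel(v0, sigma)) == pytest.approx(
            expected, rel=1e-12, abs=0.0
        )


class TestPoissonPlusApprox:
    def test_sigma_zero_reduces_to_poisson(self):
        est = pp.estimate_poisson_plus_approx(math.exp(-1.0), pp.VolumeModel(1.0, 0.0))
        assert est.c_per_volume == pytest.approx(1.0, rel=1e-12)
        assert est.model == "poisson_plus_approx"

    def test_boundary_discriminant_zero(self):
        # p_neg exactly at the validity limit: C = v0 / sigma^2
        est = pp.estimate_poisson_plus_approx(math.exp(-2.0), pp.VolumeModel(1.0, 0.5))
        assert est.c_per_volume == pytest.approx(4.0, rel=1e-9)
        assert est.at_validity_limit

    def test_closed_form_value(self):
        # (1 - sqrt(1 + 2*0.04*ln e^-1)) / 0.04, frozen from exact arithmetic
        est = pp.estimate_poisson_plus_approx(math.exp(-1.0), pp.VolumeModel(1.0, 0.2))
        assert est.c_per_volume == pytest.approx(1.0208423834364042, rel=1e-12)

    def test_below_validity_limit_raises(self):
        vol = pp.VolumeModel(1.0, 0.5)
        with pytest.raises(pp.BelowValidityLimitError):
            pp.estimate_poisson_plus_approx(0.5 * math.exp(-2.0), vol)


class TestForwardMap:
    def test_unit_probability_at_zero_concentration(self):
        for cv in (0.0, 0.1, 0.3):
            assert pp.p_negative_forward(0.0, pp.VolumeModel(755.0, cv * 755.0)) == 1.0

    def test_sigma_to_zero_limit(self):
        assert pp.p_negative_forward(1.0, pp.VolumeModel(1.0, 0.0)) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )
        # just below the numerical switch: identical route
        vol = pp.VolumeModel(1.0, 0.5 * SIGMA_SWITCH)
        assert pp.p_negative_forward(1.0, vol) == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_quadrature_frozen_value(self):
        # frozen from the quadrature oracle at c=1, v0=1, sigma=0.1
        assert pp.p_negative_forward(1.0, pp.VolumeModel(1.0, 0.1)) == pytest.approx(
            0.3697234445440590, rel=1e-12
        )

    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0, 3.0, 5.0])
    @pytest.mark.parametrize("cv", [0.05, 0.1, 0.2, 0.3])
    def test_agrees_with_quadrature_oracle(self, c, cv):
        vol = pp.VolumeModel(1.0, cv)
        assert pp.p_negative_forward(c, vol) == pytest.approx(
            truncnorm_poisson_zero_oracle(c, 1.0, cv), abs=1e-9
        )

    def test_no_overflow_at_large_concentration(self):
        vol = pp.VolumeModel(1.0, 0.1)
        vals = pp.p_negative_forward(np.array([1e2, 1e4, 1e6]), vol)
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= 0.0) and np.all(np.diff(vals) <= 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(pp.InvalidInputError):
            pp.p_negative_forward(-1.0, pp.VolumeModel(1.0, 0.1))


class TestPoissonPlusInversion:
    def test_zero_at_all_negative(self):
        est = pp.estimate_poisson_plus(1.0, pp.VolumeModel(755.0, 50.0))
        assert est.c_per_volume == 0.0

    def test_saturated_raises(self):
        with pytest.raises(pp.SaturatedChipError):
            pp.estimate_poisson_plus(0.0, pp.VolumeModel(755.0, 50.0))

    def test_round_trip_example(self):
        vol = pp.VolumeModel(1.0, 0.2)
        p = pp.p_negative_forward(1.3, vol)
        assert pp.estimate_poisson_plus(p, vol).c_per_volume == pytest.approx(
            1.3, rel=1e-8
        )

    def test_inverts_quadrature_oracle(self):
        vol = pp.VolumeModel(1.0, 0.1)
        p = truncnorm_poisson_zero_oracle(1.0, 1.0, 0.1)
        assert pp.estimate_poisson_plus(p, vol).c_per_volume == pytest.approx(
            1.0, rel=1e-7
        )


class TestUnits:
    def test_copies_per_microliter(self):
        assert pp.to_copies_per_microliter(0.0) == 0.0
        assert pp.to_copies_per_microliter(0.001) == pytest.approx(1000.0)
        # lambda = 1 at v0 = 755 pL
        est = pp.estimate_poisson(math.exp(-1.0), 755.0)
        assert est.lambda_mean == pytest.approx(1.0, rel=1e-12)
        assert est.copies_per_microliter == pytest.approx(1324.5033112582782, rel=1e-9)
        assert pp.to_copies_per_microliter(est) == est.copies_per_microliter


class TestEstimatorProperties:
    def test_monotone_decreasing_in_p_neg(self):
        vol = pp.VolumeModel(1.0, 0.2)
        grid = np.linspace(0.05, 0.99, 40)
        for fn in (
            lambda p: pp.estimate_poisson(p, 1.0).c_per_volume,
            lambda p: pp.estimate_poisson_plus_approx(p, vol).c_per_volume,
            lambda p: pp.estimate_poisson_plus(p, vol).c_per_volume,
        ):
            values = np.array([fn(p) for p in grid])
            assert np.all(np.diff(values) < 0.0)

    def test_poisson_underestimates_for_positive_sigma(self):
        vol = pp.VolumeModel(1.0, 0.25)
        for p in (0.1, 0.3, 0.5, 0.9):
            approx = pp.estimate_poisson_plus_approx(p, vol).c_per_volume
            poisson = pp.estimate_poisson(p, 1.0).c_per_volume
            assert approx > poisson
        vol0 = pp.VolumeModel(1.0, 0.0)
        assert pp.estimate_poisson_plus_approx(0.5, vol0).c_per_volume == pytest.approx(
            pp.estimate_poisson(0.5, 1.0).c_per_volume, rel=1e-14
        )

    def test_limit_equivalence_small_cv(self):
        vol = pp.VolumeModel(1.0, 1e-4)
        for p in np.arange(0.01, 1.0, 0.01):
            ref = pp.estimate_poisson(p, 1.0).c_per_volume
            for fn in (pp.estimate_poisson_plus_approx, pp.estimate_poisson_plus):
                assert fn(p, vol).c_per_volume == pytest.approx(ref, rel=1e-6)

    def test_approximation_tracks_full_model_at_moderate_cv(self):
        # erfc ratio ~ 1 for cv <= 0.1 and p_neg >= 0.1
        for cv in (0.02, 0.05, 0.1):
            vol = pp.VolumeModel(1.0, cv)
            for p in (0.1, 0.3, 0.5, 0.7, 0.9):
                full = pp.estimate_poisson_plus(p, vol).c_per_volume
                approx = pp.estimate_poisson_plus_approx(p, vol).c_per_volume
                assert abs(approx - full) / full < 1e-3

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        lam=st.floats(min_value=0.01, max_value=5.0),
        cv=st.sampled_from([0.05, 0.1, 0.2, 0.3]),
        v0=st.floats(min_value=0.5, max_value=1000.0),
    )
    def test_forward_inverse_round_trip(self, lam, cv, v0):
        vol = pp.VolumeModel(v0, cv * v0)
        c = lam / v0
        p = pp.p_negative_forward(c, vol)
        assert pp.estimate_poisson_plus(p, vol).c_per_volume == pytest.approx(
            c, rel=1e-8
        )


class TestMomentMatching:
    def test_identity_when_disabled(self):
        vol = pp.volume_model_from_moments(755.0, 75.5)
        assert (vol.v0, vol.sigma) == (755.0, 75.5)

    def test_recovers_truncnorm_parameters(self):
        from scipy import stats

        v0, sigma = 1.0, 0.45  # strong truncation: moments differ from parameters
        mean, var = stats.truncnorm.stats(-v0 / sigma, np.inf, loc=v0, scale=sigma)
        vol = pp.volume_model_from_moments(float(mean), float(np.sqrt(var)), moment_match=True)
        assert vol.v0 == pytest.approx(v0, rel=1e-6)
        assert vol.sigma == pytest.approx(sigma, rel=1e-6)


class TestBootstrapCI:
    def test_interval_brackets_point_estimate(self, rng):
        counts = pp.PartitionCounts(20000, 9000)
        vol = pp.VolumeModel(755.0, 60.4)
        lo, hi = pp.binomial_resampling_ci(counts, vol, n_boot=500, rng=rng)
        point = pp.estimate_poisson_plus(
            pp.observed_p_negative(counts), vol
        ).copies_per_microliter
        assert lo < point < hi
        assert (hi - lo) / point < 0.1
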