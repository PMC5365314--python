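"""Optical model: moments, order parameters, forward model, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberpol.orientation import (
    AngleDistribution,
    FeasibilityError,
    InversionResult,
    Moments,
    OrderParameterSet,
    PolarizedIntensitySet,
    apply_attenuation,
    forward_intensities,
    invert_intensities,
    mixture_p2,
    moments_from_distribution,
    moments_from_order_params,
    order_params_from_moments,
    project_moments,
)

from conftest import (
    oracle_gaussian_moments,
    oracle_intensities_by_integration,
    random_feasible_order_params,
)


class TestMomentsFromDistribution:
    def test_delta_parallel(self):
        m = moments_from_distribution(AngleDistribution("delta", theta0=0.0))
        assert m.m2 == 1.0 and m.m4 == 1.0

    def test_delta_perpendicular(self):
        m = moments_from_distribution(AngleDistribution("delta", theta0=90.0))
        assert m.m2 == pytest.approx(0.0, abs=1e-30)
        assert m.m4 == pytest.approx(0.0, abs=1e-30)

    def test_gaussian_matches_dense_grid_oracle(self):
        # frozen from the independent trapezoid oracle in conftest
        m = moments_from_distribution(
            AngleDistribution("gaussian_on_sphere", theta0=60.0, sigma=20.0))
        assert m.m2 == pytest.approx(0.2502284504568014, abs=1e-8)
        assert m.m4 == pytest.approx(0.1107770879278315, abs=1e-8)

    def test_gaussian_second_case_against_oracle(self):
        m = moments_from_distribution(
            AngleDistribution("gaussian_on_sphere", theta0=30.0, sigma=10.0))
        assert m.m2 == pytest.approx(0.6927217158682242, abs=1e-8)
        assert m.m4 == pytest.approx(0.5004738737993324, abs=1e-8)

    def test_live_oracle_comparison(self):
        m2o, m4o = oracle_gaussian_moments(75.0, 35.0, npts=400_001)
        m = moments_from_distribution(
            AngleDistribution("gaussian_on_sphere", theta0=75.0, sigma=35.0))
        assert m.m2 == pytest.approx(m2o, abs=1e-8)
        assert m.m4 == pytest.approx(m4o, abs=1e-8)

    def test_mixture_weight_average(self):
        sub1 = AngleDistribution("delta", theta0=0.0)
        sub2 = AngleDistribution("delta", theta0=90.0)
        mix = AngleDistribution("mixture",
                                components=[(0.25, sub1), (0.75, sub2)])
        m = moments_from_distribution(mix)
        assert m.m2 == pytest.approx(0.25, abs=1e-15)
        assert m.m4 == pytest.approx(0.25, abs=1e-15)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            AngleDistribution("gaussian_on_sphere", theta0=30.0, sigma=0.0)

    def test_bad_mixture_weights_rejected(self):
        sub = AngleDistribution("delta", theta0=10.0)
        with pytest.raises(ValueError):
            AngleDistribution("mixture", components=[(0.6, sub), (0.6, sub)])

    @settings(max_examples=25, deadline=None)
    @given(theta0=st.floats(0.0, 90.0), sigma=st.floats(1.0, 500.0))
    def test_feasibility_property(self, theta0, sigma):
        m = moments_from_distribution(
            AngleDistribution("gaussian_on_sphere", theta0=theta0, sigma=sigma))
        assert 0.0 <= m.m4 <= m.m2 <= 1.0 + 1e-12
        assert m.m4 >= m.m2 ** 2 - 1e-12


class TestOrderParams:
    def test_isotropic(self):
        ops = order_params_from_moments(Moments(m2=1.0 / 3.0, m4=1.0 / 5.0))
        assert ops.p2 == pytest.approx(0.0, abs=1e-15)
        assert ops.p4 == pytest.approx(0.0, abs=1e-15)

    def test_perpendicular(self):
        ops = order_params_from_moments(Moments(m2=0.0, m4=0.0))
        assert ops.p2 == -0.5
        assert ops.p4 == 0.375

    def test_magic_angle_delta(self):
        # delta at cos^2 = 1/3: p2 = 0, p4 = -7/18
        ops = order_params_from_moments(Moments(m2=1.0 / 3.0, m4=1.0 / 9.0))
        assert ops.p2 == pytest.approx(0.0, abs=1e-15)
        assert ops.p4 == pytest.approx(-7.0 / 18.0, abs=1e-15)

    def test_p2_bounds_attained(self):
        assert order_params_from_moments(Moments(1.0, 1.0)).p2 == 1.0
        assert order_params_from_moments(Moments(0.0, 0.0)).p2 == -0.5

    def test_infeasible_moments_named_error(self):
        with pytest.raises(FeasibilityError, match="Jensen"):
            order_params_from_moments(Moments(m2=0.5, m4=0.1))
        with pytest.raises(FeasibilityError, match="exceeds"):
            order_params_from_moments(Moments(m2=0.3, m4=0.5))


class TestForwardModel:
    def test_isotropic_components(self):
        ops = OrderParameterSet(0.0, 0.0)
        raw = forward_intensities(ops, 1.0)
        total = raw.i_pp + raw.i_pt + raw.i_tp + raw.i_tt
        ints = forward_intensities(ops, 1.0 / total)
        # isotropic signature: components in ratio 3:1:1:3
        assert ints.i_pp == pytest.approx(0.375, abs=1e-12)
        assert ints.i_pt == pytest.approx(0.125, abs=1e-12)
        assert ints.i_tp == pytest.approx(0.125, abs=1e-12)
        assert ints.i_tt == pytest.approx(0.375, abs=1e-12)

    def test_all_parallel(self):
        ints = forward_intensities(OrderParameterSet(1.0, 1.0), 7.5)
        assert ints.i_pp == pytest.approx(7.5)
        assert ints.i_pt == ints.i_tp == 0.0
        assert ints.i_tt == 0.0

    def test_all_perpendicular(self):
        k = 4.0
        ints = forward_intensities(OrderParameterSet(-0.5, 0.375), k)
        assert ints.i_pp == pytest.approx(0.0, abs=1e-15)
        assert ints.i_tt == pytest.approx(3.0 * k / 8.0)

    def test_cross_terms_equal(self):
        ints = forward_intensities(OrderParameterSet(0.21, -0.05), 3.0)
        assert ints.i_pt == ints.i_tp

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            forward_intensities(OrderParameterSet(0.0, 0.0), 0.0)

    @pytest.mark.parametrize("dist", [
        AngleDistribution("delta", theta0=35.0),
        AngleDistribution("gaussian_on_sphere", theta0=20.0, sigma=15.0),
        AngleDistribution("gaussian_on_sphere", theta0=70.0, sigma=40.0),
        AngleDistribution("mixture", components=[
            (0.3, AngleDistribution("delta", theta0=10.0)),
            (0.7, AngleDistribution("gaussian_on_sphere", theta0=55.0,
                                    sigma=25.0)),
        ]),
    ])
    def test_oracle_equivalence(self, dist):
        """Forward intensities via closed-form moments equal direct
        numerical integration of the angular weight functions."""
        scale = 2.7
        m = moments_from_distribution(dist)
        ints = forward_intensities(order_params_from_moments(m), scale)
        o_pp, o_x, o_tt = oracle_intensities_by_integration(dist, scale,
                                                            npts=400_001)
        assert ints.i_pp == pytest.approx(o_pp, abs=1e-8)
        assert ints.i_pt == pytest.approx(o_x, abs=1e-8)
        assert ints.i_tt == pytest.approx(o_tt, abs=1e-8)


class TestInversion:
    def test_round_trip_example(self):
        ints = forward_intensities(OrderParameterSet(0.3, 0.1), 2.0)
        res = invert_intensities(ints)
        assert res.ops.p2 == pytest.approx(0.3, rel=1e-10)
        assert res.ops.p4 == pytest.approx(0.1, rel=1e-10)
        assert res.scale == pytest.approx(2.0, rel=1e-10)
        assert not res.projected

    def test_round_trip_property_1000(self, rng):
        p2s, p4s = random_feasible_order_params(rng, 1000)
        scales = rng.uniform(0.1, 100.0, 1000)
        for p2, p4, s in zip(p2s, p4s, scales):
            res = invert_intensities(
                forward_intensities(OrderParameterSet(p2, p4), s))
            assert res.ops.p2 == pytest.approx(p2, rel=1e-10, abs=1e-10)
            assert res.ops.p4 == pytest.approx(p4, rel=1e-10, abs=1e-10)
            assert res.scale == pytest.approx(s, rel=1e-10)

    def test_isotropic_signature(self):
        res = invert_intensities(
            PolarizedIntensitySet(0.375, 0.125, 0.125, 0.375))
        assert res.ops.p2 == pytest.approx(0.0, abs=1e-12)
        assert res.ops.p4 == pytest.approx(0.0, abs=1e-12)

    def test_all_parallel_signature(self):
        res = invert_intensities(PolarizedIntensitySet(5.0, 0.0, 0.0, 0.0))
        assert res.ops.p2 == pytest.approx(1.0)
        assert res.ops.p4 == pytest.approx(1.0)
        assert res.scale == pytest.approx(5.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            invert_intensities(PolarizedIntensitySet(0.0, 0.0, 0.0, 0.0))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            PolarizedIntensitySet(-1.0, 0.0, 0.0, 0.0)

    def test_cross_terms_averaged_and_asymmetry_reported(self):
        base = forward_intensities(OrderParameterSet(0.2, 0.05), 1.0)
        eps = 0.01
        skew = PolarizedIntensitySet(base.i_pp, base.i_pt + eps,
                                     base.i_tp - eps, base.i_tt)
        res = invert_intensities(skew)
        # averaging restores the symmetric inversion exactly
        assert res.ops.p2 == pytest.approx(0.2, rel=1e-10)
        assert res.cross_asymmetry > 0.0

    def test_infeasible_noise_projected_and_flagged(self):
        # large cross terms with tiny i_pp force m4 < m2^2 (Jensen violation)
        res = invert_intensities(PolarizedIntensitySet(0.01, 1.0, 1.0, 0.01))
        assert res.projected
        m = moments_from_order_params(res.ops)
        m.validate(tol=1e-9)

    def test_projection_is_nearest_feasible(self):
        m = project_moments(Moments(m2=0.3, m4=0.5))
        # must land on the upper boundary m4 = m2 at the midpoint
        assert m.m2 == pytest.approx(0.4, abs=1e-12)
        assert m.m4 == pytest.approx(0.4, abs=1e-12)


class TestAttenuationAndMixtures:
    def test_identity(self):
        ops = OrderParameterSet(0.4, 0.1)
        out = apply_attenuation(ops, 1.0, 1.0)
        assert (out.p2, out.p4) == (0.4, 0.1)

    def test_direct_product(self):
        out = apply_attenuation(OrderParameterSet(1.0, 1.0), 0.8, 0.6)
        assert out.p2 == pytest.approx(0.8)
        assert out.p4 == pytest.approx(0.6)

    def test_full_disorder(self):
        out = apply_attenuation(OrderParameterSet(-0.4, 0.2), 0.0, 0.0)
        assert out.p2 == 0.0 and out.p4 == 0.0

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_attenuation(OrderParameterSet(0.1, 0.0), 1.2, 0.5)

    def test_infeasible_result_rejected(self):
        # boundary pair attenuated only in p4 can leave the feasible set
        ops = OrderParameterSet(1.0, 1.0)
        with pytest.raises(FeasibilityError):
            apply_attenuation(ops, 1.0, 0.0)

    def test_mixture_p2_examples(self):
        assert mixture_p2([0.5, 0.5], [1.0, -0.5]) == pytest.approx(0.25)
        assert mixture_p2([1.0], [0.3]) == pytest.approx(0.3)
        assert mixture_p2([0.2, 0.3, 0.5], [0.0, 0.4, -0.2]) == \
            pytest.approx(0.02, abs=1e-15)

    def test_mixture_weight_violation(self):
        with pytest.raises(ValueError):
            mixture_p2([0.5, 0.4], [0.1, 0.2])

    def test_mixture_linearity_of_intensity_sum(self, rng):
        """Observed p2 of a two-population intensity sum equals the
        weighted mixture of the component p2 values."""
        for _ in range(50):
            (p2a, p2b), (p4a, p4b) = random_feasible_order_params(rng, 2)
            w = rng.uniform(0.05, 0.95)
            s = 3.0
            ia = forward_intensities(OrderParameterSet(p2a, p4a), w * s)
            ib = forward_intensities(OrderParameterSet(p2b, p4b), (1 - w) * s)
            summed = PolarizedIntensitySet(
                ia.i_pp + ib.i_pp, ia.i_pt + ib.i_pt,
                ia.i_tp + ib.i_tp, ia.i_tt + ib.i_tt)
            res = invert_intensities(summed)
            expected = mixture_p2([w, 1 - w], [p2a, p2b])
            assert res.ops.p2 == pytest.approx(expected, abs=1e-10)

    def test_isotropy_limit_large_sigma(self):
        m = moments_from_distribution(
            AngleDistribution("gaussian_on_sphere", theta0=45.0, sigma=1e4))
        ops = order_params_from_moments(m)
        assert abs(ops.p2) < 1e-3
        assert abs(ops.p4) < 1e-3
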