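import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpmbend.exceptions import DomainError, UnattainableError
from tpmbend.params import MsdResult, PolymerParams
from tpmbend.wlc import (
    cos_coefficient,
    detection_floor,
    het_msd,
    invert_single_site,
    kinked_msd,
    piecewise_msd,
    solve_insert_lp,
)

from conftest import quad_msd_oracle


class TestKinkedMsd:
    def test_unbent_reference_value(self, geometry_mid):
        # published: 121.9 nm for 575 bp, mid bend, Lp = 150 bp
        assert kinked_msd(geometry_mid, 0.0).root == pytest.approx(121.9, abs=0.05)

    def test_rigid_rod_limit_90_degrees(self):
        # two 100 nm arms at right angle: law of cosines gives sqrt(2)*100
        g = PolymerParams(contour_length=200.0, bend_position=100.0,
                          persistence_length=2e6)
        assert kinked_msd(g, 90.0).root == pytest.approx(141.42, abs=0.05)

    def test_full_fold_derived_value(self, geometry_mid):
        # frozen from direct evaluation, cross-checked by the quadrature oracle
        res = kinked_msd(geometry_mid, 180.0)
        assert res.mean_square == pytest.approx(7283.3, abs=1.0)
        assert res.root == pytest.approx(85.3, abs=0.05)

    def test_matches_quadrature_oracle(self, geometry_318):
        g = geometry_318
        for theta in (0.0, 45.0, 117.0, 180.0):
            oracle = quad_msd_oracle(g.contour_length, g.bend_position,
                                     g.persistence_length, theta)
            assert kinked_msd(g, theta).mean_square == pytest.approx(oracle, rel=1e-6)

    def test_rigid_rod_limit_grid(self):
        L, l = 150.0, 60.0
        g = PolymerParams(contour_length=L, bend_position=l,
                          persistence_length=1e4 * L)
        for theta in range(0, 181, 30):
            exact = l**2 + (L - l)**2 + 2 * l * (L - l) * math.cos(math.radians(theta))
            assert kinked_msd(g, theta).mean_square == pytest.approx(exact, rel=1e-3)

    def test_gaussian_limit(self):
        lp = 2.0
        g = PolymerParams(contour_length=100 * lp * 100, bend_position=lp,
                          persistence_length=lp)
        ratio = kinked_msd(g, 0.0).mean_square / (2 * g.contour_length * lp)
        assert ratio == pytest.approx(1.0, rel=0.03)

    @settings(max_examples=30, deadline=None)
    @given(
        length=st.floats(min_value=20.0, max_value=2000.0),
        frac=st.floats(min_value=0.05, max_value=0.95),
        lp=st.floats(min_value=5.0, max_value=500.0),
    )
    def test_strictly_decreasing_in_theta(self, length, frac, lp):
        g = PolymerParams(contour_length=length, bend_position=frac * length,
                          persistence_length=lp)
        thetas = np.linspace(0.0, 180.0, 19)
        values = [kinked_msd(g, t).mean_square for t in thetas]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_domain_errors(self, geometry_mid):
        with pytest.raises(DomainError):
            kinked_msd(geometry_mid, -1.0)
        with pytest.raises(DomainError):
            kinked_msd(geometry_mid, 181.0)
        with pytest.raises(DomainError):
            kinked_msd(geometry_mid, float("nan"))

    def test_msd_result_root_consistency(self, geometry_mid):
        res = kinked_msd(geometry_mid, 30.0)
        assert res.root == pytest.approx(math.sqrt(res.mean_square))
        assert isinstance(res, MsdResult)


class TestCosCoefficient:
    def test_mid_bend_published(self, geometry_mid):
        assert cos_coefficient(geometry_mid) == pytest.approx(0.342, abs=5e-4)

    def test_offset_bend_published(self, geometry_318):
        assert cos_coefficient(geometry_318) == pytest.approx(0.338, abs=5e-4)

    def test_rigid_mid_limit_is_one(self):
        g = PolymerParams(contour_length=100.0, bend_position=50.0,
                          persistence_length=1e7)
        assert cos_coefficient(g) == pytest.approx(1.0, abs=1e-4)

    def test_reduced_form_identity(self, geometry_318):
        # R(theta) must equal D*sqrt(1 + c*cos(theta)) with D = R(90 deg)
        c = cos_coefficient(geometry_318)
        d = kinked_msd(geometry_318, 90.0).root
        for theta in (0.0, 60.0, 150.0):
            expected = d * math.sqrt(1 + c * math.cos(math.radians(theta)))
            assert kinked_msd(geometry_318, theta).root == pytest.approx(expected, rel=1e-12)


class TestInvertSingleSite:
    def test_ihf_clamped_180(self):
        g = PolymerParams.from_bp(1943, 301, 150)
        inv = invert_single_site(229.0, 249.0, g)
        assert inv.theta == pytest.approx(180.0)
        assert inv.clamped
        assert inv.raw_cos < -1.0

    def test_no_change_gives_zero(self, geometry_318):
        inv = invert_single_site(105.4, 105.4, geometry_318)
        assert inv.theta == pytest.approx(0.0)
        assert not inv.clamped

    def test_four_insert_derived_value(self, geometry_318):
        inv = invert_single_site(98.5, 105.4, geometry_318)
        assert inv.theta == pytest.approx(60.1, abs=0.05)
        assert inv.theta / 4 == pytest.approx(15.0, abs=0.05)

    @settings(max_examples=25, deadline=None)
    @given(theta=st.floats(min_value=1.0, max_value=179.0))
    def test_round_trip(self, theta):
        g = PolymerParams.from_bp(575, 318, 150)
        r_bent = kinked_msd(g, theta).root
        r0 = kinked_msd(g, 0.0).root
        inv = invert_single_site(r_bent, r0, g)
        assert inv.theta == pytest.approx(theta, abs=1e-6)
        assert not inv.clamped

    def test_domain_errors(self, geometry_318):
        with pytest.raises(DomainError):
            invert_single_site(100.0, 0.0, geometry_318)
        with pytest.raises(DomainError):
            invert_single_site(-5.0, 100.0, geometry_318)


class TestDetectionFloor:
    def test_two_percent_published(self, geometry_318):
        assert round(detection_floor(0.02, geometry_318)) == 33

    def test_zero_change(self, geometry_318):
        assert detection_floor(0.0, geometry_318) == pytest.approx(0.0)

    def test_five_percent_derived(self, geometry_318):
        assert detection_floor(0.05, geometry_318) == pytest.approx(52.1, abs=0.05)

    def test_independent_of_scale(self, geometry_318):
        # definitionally scale-free; spot-check through the raw inversion
        for r0 in (50.0, 250.0):
            inv = invert_single_site(0.97 * r0, r0, geometry_318)
            assert inv.theta == pytest.approx(detection_floor(0.03, geometry_318))

    def test_domain_error(self, geometry_318):
        with pytest.raises(DomainError):
            detection_floor(1.0, geometry_318)
        with pytest.raises(DomainError):
            detection_floor(-0.1, geometry_318)


class TestHetMsd:
    def test_uniform_reduces_to_kinked(self, geometry_mid):
        g = geometry_mid
        res = het_msd(g.contour_length, 10.0, 25.0,
                      g.persistence_length, g.persistence_length)
        assert res.mean_square == pytest.approx(
            kinked_msd(g, 0.0).mean_square, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        res = het_msd(195.5, (195.5 - 18.7) / 2, 18.7, 51.0, 129.0)
        oracle = quad_msd_oracle(195.5, None, 51.0, 0.0,
                                 lp_insert=129.0,
                                 insert=((195.5 - 18.7) / 2, 18.7))
        assert res.mean_square == pytest.approx(oracle, rel=1e-4)

    def test_monotone_in_insert_stiffness(self):
        values = [het_msd(195.5, 80.0, 20.0, 51.0, lp).mean_square
                  for lp in (51.0, 80.0, 129.0, 500.0, 1e6)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_small_insert_linear_growth(self):
        # delta-R vs insert length is linear to first order: the second
        # difference is negligible against the first difference
        base = het_msd(195.5, 90.0, 1e-9, 51.0, 129.0).root
        lengths = np.array([2.0, 4.0, 6.0, 8.0])
        deltas = np.array([
            het_msd(195.5, 90.0, ln, 51.0, 129.0).root - base for ln in lengths
        ])
        slopes = np.diff(deltas) / np.diff(lengths)
        assert np.all(slopes > 0)
        assert abs(slopes[-1] - slopes[0]) / slopes[0] < 0.05

    def test_piecewise_segment_split_invariance(self):
        # splitting a uniform chain into segments must not change the result
        one = piecewise_msd([(100.0, 40.0)])
        many = piecewise_msd([(20.0, 40.0)] * 5)
        assert many.mean_square == pytest.approx(one.mean_square, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            het_msd(100.0, 50.0, 60.0, 51.0, 129.0)
        with pytest.raises(DomainError):
            het_msd(100.0, 10.0, 10.0, -1.0, 129.0)


class TestSolveInsertLp:
    def test_zero_delta(self):
        assert solve_insert_lp(0.0, 195.5, 88.4, 18.7, 51.0) == pytest.approx(51.0)

    def test_published_insert_soft_check(self):
        # 3.2 nm increase over a 55 bp centred insert: a persistence length
        # well above 100 nm (soft check against the published 129 nm scale)
        lp = solve_insert_lp(3.2, 195.5, (195.5 - 18.7) / 2, 18.7, 51.0)
        assert lp > 100.0
        # round trip
        got = (het_msd(195.5, (195.5 - 18.7) / 2, 18.7, 51.0, lp).root
               - het_msd(195.5, (195.5 - 18.7) / 2, 18.7, 51.0, 51.0).root)
        assert got == pytest.approx(3.2, abs=1e-6)

    def test_monotone_in_delta(self):
        lps = [solve_insert_lp(d, 195.5, 88.4, 18.7, 51.0) for d in (0.5, 1.5, 3.0)]
        assert lps[0] < lps[1] < lps[2]

    def test_unreachable_delta(self):
        with pytest.raises(UnattainableError):
            solve_insert_lp(500.0, 195.5, 88.4, 18.7, 51.0)


class TestOracleEquivalence:
    def test_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            L = rng.uniform(60, 400)
            l = rng.uniform(0.1, 0.9) * L
            lp = rng.uniform(15, 120)
            theta = rng.uniform(0, 180)
            g = PolymerParams(contour_length=L, bend_position=l, persistence_length=lp)
            oracle = quad_msd_oracle(L, l, lp, theta)
            assert kinked_msd(g, theta).mean_square == pytest.approx(oracle, rel=1e-4)
        for _ in range(5):
            L = rng.uniform(60, 400)
            start = rng.uniform(0.05, 0.5) * L
            ln = rng.uniform(0.05, 0.4) * L
            lp_f = rng.uniform(20, 80)
            lp_i = rng.uniform(lp_f, 300)
            oracle = quad_msd_oracle(L, None, lp_f, 0.0, lp_insert=lp_i,
                                     insert=(start, ln))
            assert het_msd(L, start, ln, lp_f, lp_i).mean_square == pytest.approx(
                oracle, rel=1e-4)
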