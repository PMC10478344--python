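"""Closed-form SSM fitting, polar conversions and interpretation gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circumplex_ssm import (
    Cutoffs,
    apply_cutoffs,
    correlation_profile,
    polar_from_vectors,
    signed_angle_diff,
    ssm_from_correlations,
)
from circumplex_ssm.geometry import OctantGeometry


def cosine_profile(e, a, theta, angles):
    return e + a * np.cos(np.deg2rad(angles - theta))


def lstsq_oracle(r, angles_deg):
    """Independent least-squares fit of e + b1*cos + b2*sin."""
    rad = np.deg2rad(angles_deg)
    X = np.column_stack([np.ones_like(rad), np.cos(rad), np.sin(rad)])
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    e, x, y = coef
    a = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360
    fitted = X @ coef
    ss_res = np.sum((r - fitted) ** 2)
    ss_tot = np.sum((r - np.mean(r)) ** 2)
    return e, x, y, a, theta, 1 - ss_res / ss_tot


class TestClosedForm:
    def test_exact_cosine_profile(self, geometry):
        r = cosine_profile(0.3, 0.2, 90.0, geometry.angles_deg)
        p = ssm_from_correlations(r, geometry.angles_deg)
        assert p.e == pytest.approx(0.3)
        assert p.a == pytest.approx(0.2)
        assert p.theta == pytest.approx(90.0)
        assert p.r2 == pytest.approx(1.0)

    def test_flat_profile_has_undefined_r2_and_angle(self, geometry):
        with pytest.warns(UserWarning, match="flat profile"):
            p = ssm_from_correlations(np.full(8, 0.25), geometry.angles_deg)
        assert p.e == pytest.approx(0.25)
        assert p.a == pytest.approx(0.0)
        assert np.isnan(p.theta)
        assert np.isnan(p.r2)

    def test_matches_least_squares_oracle_on_fixed_profile(self, geometry):
        r = np.array([0.10, 0.20, 0.30, 0.20, 0.10, 0.00, -0.10, 0.00])
        p = ssm_from_correlations(r, geometry.angles_deg)
        e, x, y, a, theta, r2 = lstsq_oracle(r, geometry.angles_deg)
        assert p.e == pytest.approx(e, abs=1e-12)
        assert p.x == pytest.approx(x, abs=1e-12)
        assert p.y == pytest.approx(y, abs=1e-12)
        assert p.a == pytest.approx(a, abs=1e-12)
        assert p.theta == pytest.approx(theta, abs=1e-10)
        assert p.r2 == pytest.approx(r2, abs=1e-12)

    def test_matches_least_squares_oracle_on_random_profiles(self, geometry):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r = rng.uniform(-0.9, 0.9, size=8)
            p = ssm_from_correlations(r, geometry.angles_deg)
            e, x, y, a, theta, r2 = lstsq_oracle(r, geometry.angles_deg)
            assert max(abs(p.e - e), abs(p.x - x), abs(p.y - y), abs(p.a - a)) < 1e-8
            assert abs(signed_angle_diff(p.theta, theta)) < 1e-8
            assert abs(p.r2 - r2) < 1e-8

    def test_matches_brute_force_grid(self, geometry):
        # coarse grid search over (e, a, theta) minimizing squared error
        rng = np.random.default_rng(1)
        r = rng.uniform(-0.5, 0.5, size=8)
        p = ssm_from_correlations(r, geometry.angles_deg)
        es = np.linspace(p.e - 0.05, p.e + 0.05, 21)
        as_ = np.linspace(max(p.a - 0.05, 0), p.a + 0.05, 21)
        ths = np.arange(0.0, 360.0, 1.0)
        best = None
        for e in es:
            for a in as_:
                fitted = e + a * np.cos(np.deg2rad(geometry.angles_deg[None, :] - ths[:, None]))
                sse = ((r[None, :] - fitted) ** 2).sum(axis=1)
                i = np.argmin(sse)
                if best is None or sse[i] < best[0]:
                    best = (sse[i], e, a, ths[i])
        _, e, a, th = best
        assert p.e == pytest.approx(e, abs=0.006)
        assert p.a == pytest.approx(a, abs=0.006)
        assert abs(signed_angle_diff(p.theta, th)) <= 1.0

    def test_refit_idempotence(self, geometry):
        rng = np.random.default_rng(2)
        r = rng.uniform(-0.6, 0.6, size=8)
        p = ssm_from_correlations(r, geometry.angles_deg)
        fitted = cosine_profile(p.e, p.a, p.theta, geometry.angles_deg)
        p2 = ssm_from_correlations(fitted, geometry.angles_deg)
        assert p2.e == pytest.approx(p.e)
        assert p2.a == pytest.approx(p.a)
        assert abs(signed_angle_diff(p2.theta, p.theta)) < 1e-8
        assert p2.r2 == pytest.approx(1.0)


@st.composite
def profiles(draw):
    return np.array([draw(st.floats(-0.9, 0.9)) for _ in range(8)])


class TestEquivariance:
    @settings(max_examples=60, deadline=None)
    @given(r=profiles(), phi=st.floats(0.0, 360.0))
    def test_rotation_shifts_theta_only(self, r, phi):
        geometry = OctantGeometry()
        base = ssm_from_correlations(r, geometry.angles_deg)
        rotated = ssm_from_correlations(r, geometry.angles_deg + phi)
        assert rotated.e == pytest.approx(base.e, abs=1e-9)
        assert rotated.a == pytest.approx(base.a, abs=1e-9)
        if base.a > 1e-6:
            assert abs(signed_angle_diff(rotated.theta, (base.theta + phi) % 360)) < 1e-5
            assert rotated.r2 == pytest.approx(base.r2, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(r=profiles())
    def test_reflection_mirrors_theta(self, r):
        geometry = OctantGeometry()
        base = ssm_from_correlations(r, geometry.angles_deg)
        reflected = ssm_from_correlations(r, -geometry.angles_deg)
        assert reflected.e == pytest.approx(base.e, abs=1e-9)
        assert reflected.a == pytest.approx(base.a, abs=1e-9)
        if base.a > 1e-6:
            assert abs(signed_angle_diff(reflected.theta, (360 - base.theta) % 360)) < 1e-5

    @settings(max_examples=60, deadline=None)
    @given(r=profiles(), c=st.floats(-0.1, 0.1), s=st.floats(0.1, 1.0))
    def test_affine_profile_transformations(self, r, c, s):
        geometry = OctantGeometry()
        base = ssm_from_correlations(r, geometry.angles_deg)
        shifted = ssm_from_correlations(r + c, geometry.angles_deg)
        scaled = ssm_from_correlations(r * s, geometry.angles_deg)
        assert shifted.e == pytest.approx(base.e + c, abs=1e-9)
        assert shifted.a == pytest.approx(base.a, abs=1e-9)
        assert scaled.e == pytest.approx(base.e * s, abs=1e-9)
        assert scaled.a == pytest.approx(base.a * s, abs=1e-9)
        if base.a > 1e-6:
            assert abs(signed_angle_diff(scaled.theta, base.theta)) < 1e-6
            assert scaled.r2 == pytest.approx(base.r2, abs=1e-7)

    @settings(max_examples=60, deadline=None)
    @given(r=profiles())
    def test_elevation_is_profile_mean(self, r):
        geometry = OctantGeometry()
        assert ssm_from_correlations(r, geometry.angles_deg).e == pytest.approx(
            float(np.mean(r)), abs=1e-12
        )


class TestCorrelationProfile:
    def test_self_correlation_is_one(self, geometry):
        rng = np.random.default_rng(0)
        octants = pd.DataFrame(rng.standard_normal((50, 8)), columns=list(geometry.codes))
        scale = octants["PA"].rename("pa_copy")
        prof = correlation_profile(scale, octants)
        assert prof.r[0] == pytest.approx(1.0)

    def test_independent_scale_has_small_correlations(self, geometry):
        rng = np.random.default_rng(1)
        octants = pd.DataFrame(rng.standard_normal((5000, 8)), columns=list(geometry.codes))
        scale = pd.Series(rng.standard_normal(5000), name="noise")
        prof = correlation_profile(scale, octants)
        assert np.all(np.abs(prof.r) < 0.05)

    def test_constant_scale_raises(self, geometry):
        rng = np.random.default_rng(2)
        octants = pd.DataFrame(rng.standard_normal((30, 8)), columns=list(geometry.codes))
        scale = pd.Series(np.ones(30), name="flatline")
        with pytest.raises(ValueError, match="flatline.*constant"):
            correlation_profile(scale, octants)

    def test_pairwise_complete_counts(self, geometry):
        rng = np.random.default_rng(3)
        octants = pd.DataFrame(rng.standard_normal((40, 8)), columns=list(geometry.codes))
        octants.iloc[:5, 0] = np.nan
        scale = pd.Series(rng.standard_normal(40), name="s", index=octants.index)
        prof = correlation_profile(scale, octants)
        assert prof.n_pairs[0] == 35
        assert prof.n_pairs[1] == 40


class TestPolarAndCutoffs:
    @pytest.mark.parametrize(
        "x, y, amp, theta",
        [
            # amplitudes recomputed from published communion/agency pairs
            (-0.28, -0.02, 0.28, 184.1),
            (0.17, -0.0, 0.17, None),  # angle indistinguishable from 0/360
            (0.0, 0.5, 0.5, 90.0),
        ],
    )
    def test_polar_from_vectors(self, x, y, amp, theta):
        a, th = polar_from_vectors(x, y)
        assert round(a, 2) == amp
        if theta is not None:
            assert abs(signed_angle_diff(th, theta)) < 0.1

    def test_zero_vector_has_no_angle(self):
        a, th = polar_from_vectors(0.0, 0.0)
        assert a == 0.0
        assert np.isnan(th)

    @pytest.mark.parametrize(
        "e, a, r2, flags",
        [
            # strong cold profile: everything interpretable
            (0.19, 0.28, 0.937, (True, True, True, True)),
            # complex profile: nothing beyond elevation
            (0.34, 0.05, 0.486, (True, False, False, False)),
            # prototypical but undifferentiated: angle not interpreted
            (0.17, 0.09, 0.937, (True, True, False, False)),
            # differentiated but not elevated
            (0.05, 0.21, 0.892, (False, True, True, True)),
        ],
    )
    def test_apply_cutoffs(self, e, a, r2, flags):
        from circumplex_ssm import SSMParams

        ruling = apply_cutoffs(SSMParams(e=e, x=0, y=0, a=a, theta=0.0, r2=r2))
        assert (ruling.elevated, ruling.prototypical, ruling.differentiated,
                ruling.angle_interpretable) == flags

    def test_ruling_implication_invariant(self):
        from circumplex_ssm import SSMParams

        rng = np.random.default_rng(9)
        for _ in range(200):
            p = SSMParams(e=rng.uniform(-0.5, 0.5), x=0, y=0,
                          a=rng.uniform(0, 0.5), theta=0.0, r2=rng.uniform(0, 1))
            ruling = apply_cutoffs(p)
            if ruling.angle_interpretable:
                assert ruling.prototypical and ruling.differentiated

    def test_cutoffs_must_be_positive(self):
        with pytest.raises(ValueError):
            Cutoffs(r2_min=0.0)
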