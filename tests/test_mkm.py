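"""MKM survival/EQDX conversions, VOI aggregation and dose-mass
histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tatdose.mkm import (
    MKMParams,
    dmh,
    eqdx,
    eqdx_map,
    rbe_limit_ratio,
    recovery_factor,
    survival,
    voi_survival,
)
from tatdose.microspec import LinealSpectrum


class TestRecoveryFactor:
    def test_no_recovery_limit(self):
        assert recovery_factor(0.1, 0.0, mu=0.0) == 1.0

    def test_hand_value(self):
        # lambda_phy = 0.0961 (7.2 h half-life), no clearance, mu = 1.5
        assert recovery_factor(0.0961, 0.0, 1.5) == pytest.approx(0.06021, abs=1e-5)

    def test_instantaneous_delivery_limit(self):
        assert recovery_factor(1e9, 0.0, 1.5) == pytest.approx(1.0, rel=1e-6)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            recovery_factor(0.0, 0.0, 1.5)

    @given(
        lam=st.floats(min_value=1e-3, max_value=100.0),
        mu=st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, lam, mu):
        g = recovery_factor(lam, 0.0, mu)
        assert 0.0 < g <= 1.0


class TestSurvival:
    def test_zero_dose(self, params):
        assert survival(0.0, 10.0, 1.0, params) == 1.0

    def test_reference_fraction(self, params_cal):
        # z* = z*_ref collapses the linear term to alpha: S = exp(-aX-bX^2)
        p = params_cal
        s = survival(p.X, p.z_star_ref, 1.0, p)
        assert s == pytest.approx(np.exp(-(p.alpha * 2 + p.beta * 4)), rel=1e-12)
        assert s == pytest.approx(np.exp(-0.748), rel=1e-12)

    def test_hand_value_high_let(self):
        # alpha0 = 0.13, z* = 36.4 Gy, D = 1 Gy, G = 1
        p = MKMParams(z_star_ref=(0.251 - 0.13) / 0.0615)
        assert p.alpha0 == pytest.approx(0.13, rel=1e-12)
        s = survival(1.0, 36.4, 1.0, p)
        assert s == pytest.approx(np.exp(-(0.13 + 0.0615 * 36.4 + 0.0615)), rel=1e-9)
        assert s == pytest.approx(0.0880, abs=2e-4)


class TestEqdx:
    def test_no_effect_no_dose(self, params):
        assert eqdx(1.0, params) == 0.0

    def test_unit_dose_hand_value(self, params):
        assert eqdx(np.exp(-0.374), params) == pytest.approx(1.0, rel=1e-9)

    def test_reference_self_consistency(self, params_cal):
        """A single reference fraction of size X maps to EQDX = X."""
        p = params_cal
        s = survival(p.X, p.z_star_ref, 1.0, p)
        assert eqdx(s, p) == pytest.approx(p.X, rel=1e-9)

    def test_exact_inverse_of_survival_for_reference_treatment(self, params_cal):
        """A total dose D delivered by the reference treatment in
        fractions of size X has ln S = -(alpha + beta X) D; eqdx inverts
        it exactly over [0, 20] Gy."""
        p = params_cal
        doses = np.linspace(0.0, 20.0, 41)
        s = np.exp(-p.reference_slope * doses)
        back = eqdx(s, p)
        assert np.allclose(back, doses, rtol=1e-9, atol=1e-12)
        # single-fraction case: survival() itself reproduces one fraction
        s_one = survival(p.X, p.z_star_ref, 1.0, p)
        assert eqdx(s_one, p) == pytest.approx(p.X, rel=1e-9)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            eqdx(0.0, params)
        with pytest.raises(ValueError):
            eqdx(1.5, params)


class TestRbeLimit:
    def test_reference_value(self, params_cal):
        p = params_cal
        ratio = rbe_limit_ratio(p.z_star_ref, p)
        assert ratio == pytest.approx(p.alpha / (p.alpha + p.beta * p.X), rel=1e-12)
        assert ratio == pytest.approx(0.671, abs=1e-3)

    def test_strictly_increasing_in_z_star(self, params_cal):
        z = np.linspace(0, 50, 20)
        vals = [rbe_limit_ratio(zz, params_cal) for zz in z]
        assert np.all(np.diff(vals) > 0)


class TestVoiAggregation:
    def test_identical_voxels(self, params):
        s = np.full(10, 0.3)
        m = np.full(10, 2.0)
        assert voi_survival(s, m) == pytest.approx(0.3, rel=1e-12)

    def test_two_voxel_zero_ten_gy_hand_value(self, params):
        """Equal-mass voxels at 0 and 10 Gy of reference-quality
        radiation: S_VOI ~ 0.50009 and EQDX_VOI ~ 1.853 Gy, far below the
        5 Gy uniform-dose EQDX."""
        p = params
        s = survival(np.array([0.0, 10.0]), p.z_star_ref, 1.0, p)
        s_voi = voi_survival(s, np.ones(2))
        assert s_voi == pytest.approx((1 + np.exp(-(0.251 * 10 + 0.0615 * 100))) / 2, rel=1e-9)
        assert s_voi == pytest.approx(0.50009, abs=1e-5)
        e_voi = eqdx(s_voi, p)
        assert e_voi == pytest.approx(1.853, abs=2e-3)
        e_uniform = eqdx(survival(5.0, p.z_star_ref, 1.0, p), p)
        assert e_voi < e_uniform

    def test_reorder_invariance(self):
        s = np.array([0.9, 0.5, 0.1])
        m = np.array([1.0, 2.0, 3.0])
        perm = [2, 0, 1]
        assert voi_survival(s, m) == pytest.approx(voi_survival(s[perm], m[perm]), rel=1e-14)

    def test_empty_voi_errors(self):
        with pytest.raises(ValueError):
            voi_survival(np.array([]), np.array([]))

    @given(
        d1=st.floats(min_value=2.0, max_value=30.0),
        d2=st.floats(min_value=2.0, max_value=30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_heterogeneity_never_increases_eqdx(self, params_cal, d1, d2):
        """EQDX_VOI <= EQDX of the uniform field with the same
        mass-weighted mean dose, for high-dose two-voxel fields."""
        p = params_cal
        s = survival(np.array([d1, d2]), p.z_star_ref, 1.0, p)
        e_voi = eqdx(voi_survival(s, np.ones(2)), p)
        mean_d = (d1 + d2) / 2
        e_mean = eqdx(survival(mean_d, p.z_star_ref, 1.0, p), p)
        assert e_voi <= e_mean + 1e-9

    @given(
        d=st.floats(min_value=0.1, max_value=30.0),
        lam=st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ignoring_dose_rate_effect_never_decreases_eqdx(self, params_cal, d, lam):
        p = params_cal
        g = recovery_factor(lam, 0.0, p.mu)
        e_full = eqdx(survival(d, p.z_star_ref, g, p), p)
        e_mu0 = eqdx(survival(d, p.z_star_ref, 1.0, p), p)
        assert e_mu0 >= e_full - 1e-12


def _unit_spectrum(y_value):
    return LinealSpectrum(
        y_edges=np.array([y_value * 0.999, y_value * 1.001]),
        density=np.array([1 / (0.002 * y_value)]),
        component="beta", nuclide="unit", n_samples=0, seed=None,
    )


class TestEqdxMap:
    def test_uniform_field_matches_scalar_pipeline(self, params_cal):
        from tatdose.microspec import z_star_1d

        p = params_cal
        spec_b = _unit_spectrum(1.5)
        db = np.full((4, 4, 4), 2.0)
        da = np.zeros_like(db)
        out = eqdx_map(da, db, None, spec_b, p, lambda_phy=0.38)
        zb = z_star_1d(spec_b, p.geom)
        g = recovery_factor(0.38, 0.0, p.mu)
        expected = eqdx(survival(2.0, zb, g, p), p)
        assert np.allclose(out, expected, rtol=1e-12)

    def test_doubling_dose_does_not_double_eqdx(self, params_cal):
        p = params_cal
        spec_b = _unit_spectrum(1.5)
        d1 = np.full((2, 2, 2), 3.0)
        e1 = eqdx_map(np.zeros_like(d1), d1, None, spec_b, p, 0.38)
        e2 = eqdx_map(np.zeros_like(d1), 2 * d1, None, spec_b, p, 0.38)
        assert np.all(e2 > 2 * e1)  # quadratic term

    def test_zero_dose_voxels_get_zero(self, params_cal):
        spec_b = _unit_spectrum(1.5)
        db = np.zeros((3, 3, 3))
        db[1, 1, 1] = 1.0
        out = eqdx_map(np.zeros_like(db), db, None, spec_b, params_cal, 0.38)
        assert out[0, 0, 0] == 0.0 and out[1, 1, 1] > 0

    def test_shape_mismatch_errors(self, params_cal):
        spec_b = _unit_spectrum(1.5)
        with pytest.raises(ValueError):
            eqdx_map(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)), None, spec_b, params_cal, 0.38)


class TestDmh:
    def test_uniform_dose_step(self):
        edges, frac = dmh(np.full(8, 3.0), np.ones(8), np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(frac, [1, 1, 1, 1, 0])

    def test_starts_at_one_and_monotone(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(2.0, 100)
        m = rng.uniform(0.5, 2.0, 100)
        edges, frac = dmh(d, m, np.linspace(0, 20, 50))
        assert frac[0] == 1.0
        assert np.all(np.diff(frac) <= 0)

    def test_mean_dose_recovered_from_integral(self):
        # integral of DMH(d) dd equals the mass-weighted mean dose
        rng = np.random.default_rng(1)
        d = rng.gamma(2.0, 1.5, 500)
        m = rng.uniform(0.5, 2.0, 500)
        edges = np.linspace(0, d.max() * 1.01, 4000)
        _, frac = dmh(d, m, edges)
        integral = np.trapezoid(frac, edges)
        mean = np.sum(d * m) / m.sum()
        assert integral == pytest.approx(mean, rel=2e-3)


def test_params_json_roundtrip(tmp_path):
    p = MKMParams(z_star_ref=1.1)
    path = tmp_path / "params.json"
    p.to_json(path)
    q = MKMParams.from_json(path)
    assert q == p
    assert q.alpha0 == pytest.approx(0.251 - 0.0615 * 1.1, rel=1e-12)


def test_negative_alpha0_warns():
    with pytest.warns(UserWarning):
        MKMParams(z_star_ref=10.0)
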