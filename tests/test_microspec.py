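"""Lineal-energy spectra: chord sampling, LET interpolation, the dose
probability density sampler and the saturation-corrected moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tatdose.constants import KEV_PER_UM3_TO_GY
from tatdose.decay import EmissionLine, Nuclide
from tatdose.microspec import (
    DomainGeometry,
    LinealSpectrum,
    chord_pdf_sample,
    compute_dose_pd,
    default_y_edges,
    mix_spectra,
    reference_electron_spectrum,
    stopping_power,
    y_star,
    z_star_1d,
)


class TestChordSampling:
    def test_mean_chord_converges_to_cauchy_value(self):
        r = 0.282
        l = chord_pdf_sample(r, 200_000, seed=1)
        assert l.mean() == pytest.approx(4 * r / 3, rel=5e-3)

    def test_support_is_diameter(self):
        l = chord_pdf_sample(0.282, 50_000, seed=2)
        assert l.min() >= 0 and l.max() <= 2 * 0.282

    def test_cdf_quarter_at_radius(self):
        # F(l) = l^2 / (4 r^2), so F(r) = 1/4
        r = 0.282
        l = chord_pdf_sample(r, 200_000, seed=3)
        assert np.mean(l <= r) == pytest.approx(0.25, abs=5e-3)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            chord_pdf_sample(-1.0, 10, seed=0)
        with pytest.raises(ValueError):
            chord_pdf_sample(1.0, 0, seed=0)


class TestStoppingPower:
    def test_interpolation_identity_at_tabulated_point(self):
        # 5.5 MeV alpha row of the embedded table
        assert stopping_power("alpha", 5.5) == pytest.approx(89.5, rel=1e-12)

    def test_alpha_let_decreases_above_bragg_peak(self):
        assert stopping_power("alpha", 0.8) > stopping_power("alpha", 7.0)

    def test_electron_let_far_below_alpha_let(self):
        assert stopping_power("electron", 0.25) < 0.01 * stopping_power("alpha", 6.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            stopping_power("alpha", 1e4)
        with pytest.raises(ValueError):
            stopping_power("electron", 1e-6)
        with pytest.raises(ValueError):
            stopping_power("muon", 1.0)


def _constant_let_spectrum(geom, let=100.0, n=200_000, seed=7):
    """Fictitious emitter with constant LET and a track far longer than
    the domain diameter."""
    nuc = Nuclide(
        name="const-let",
        half_life=1.0,
        emissions=(EmissionLine("alpha", 1000.0, 1.0),),
    )
    return compute_dose_pd(
        nuc, "alpha", geom, n_samples=n, seed=seed,
        stopping_override=lambda p, e: np.full(np.shape(e), let),
    )


class TestDosePd:
    def test_constant_let_dose_mean_is_nine_eighths_let(self, geom):
        # closed form: y = L l / lbar with dose weight ~ l gives
        # mean = L * E[l^2] / (lbar E[l]) = (9/8) L
        spec = _constant_let_spectrum(geom, let=100.0)
        assert spec.dose_mean_y() == pytest.approx(9 / 8 * 100.0, rel=5e-3)

    def test_constant_let_density_matches_analytic_transform(self, geom):
        # d(y) = 3 y^2 / ymax^3 on [0, ymax], ymax = 1.5 L; its CDF at
        # ymax/2 is 1/8
        let = 100.0
        spec = _constant_let_spectrum(geom, let=let)
        ymax = 2 * geom.r_d * let / geom.mean_chord
        below = spec.y_mid < ymax / 2
        cdf_half = float(np.sum((spec.density * spec.dy)[below]))
        assert cdf_half == pytest.approx(1 / 8, abs=0.01)

    def test_normalization(self, geom, at211_inventory, f18):
        for spec in (
            compute_dose_pd(at211_inventory, "alpha", geom, 50_000, seed=4),
            compute_dose_pd(f18, "beta", geom, 50_000, seed=5),
        ):
            assert spec.norm() == pytest.approx(1.0, abs=1e-6)

    def test_fixed_seed_is_bit_reproducible(self, geom, f18):
        a = compute_dose_pd(f18, "beta", geom, 20_000, seed=11)
        b = compute_dose_pd(f18, "beta", geom, 20_000, seed=11)
        assert np.array_equal(a.density, b.density)

    def test_empty_component_errors(self, geom, f18):
        with pytest.raises(ValueError, match="no emissions"):
            compute_dose_pd(f18, "alpha", geom, 1000, seed=0)

    def test_at211_alpha_support_above_f18_beta_support(self, geom, at211_inventory, f18):
        """The alpha spectrum concentrates at tens of keV/um while the
        F-18 beta spectrum lies below ~15 keV/um (qualitative ordering)."""
        sa = compute_dose_pd(at211_inventory, "alpha", geom, 50_000, seed=6)
        sb = compute_dose_pd(f18, "beta", geom, 50_000, seed=7)
        w_a = sa.density * sa.dy
        w_b = sb.density * sb.dy
        assert np.sum(w_a[(sa.y_mid > 40) & (sa.y_mid < 400)]) > 0.7
        assert np.sum(w_b[sb.y_mid < 15]) > 0.9


class TestSaturationMoments:
    def test_monoenergetic_at_y0_closed_form(self):
        # y* = y0 (1 - 1/e) = 59.04 keV/um for a line at y = y0 = 93.4
        y0 = 93.4
        spec = LinealSpectrum(
            y_edges=np.array([y0 - 0.1, y0 + 0.1]),
            density=np.array([1 / 0.2]),
            component="beta", nuclide="mono", n_samples=0, seed=None,
        )
        assert y_star(spec, y0) == pytest.approx(y0 * (1 - np.exp(-1)), abs=0.01)
        assert y_star(spec, y0) == pytest.approx(59.04, abs=0.01)

    def test_large_y0_limit_is_dose_mean(self, geom, at211_inventory):
        spec = compute_dose_pd(at211_inventory, "alpha", geom, 50_000, seed=8)
        assert y_star(spec, 1e6) == pytest.approx(spec.dose_mean_y(), rel=1e-3)

    def test_saturation_only_reduces(self, geom, at211_inventory):
        spec = compute_dose_pd(at211_inventory, "alpha", geom, 50_000, seed=9)
        assert y_star(spec, geom.y0) <= spec.dose_mean_y()

    @given(st.floats(min_value=10.0, max_value=1e5))
    @settings(max_examples=30, deadline=None)
    def test_y_star_monotone_in_y0(self, y0):
        spec = LinealSpectrum(
            y_edges=default_y_edges(50),
            density=np.ones(50) / np.diff(default_y_edges(50)).sum(),
            component="beta", nuclide="flat", n_samples=0, seed=None,
        )
        # normalize properly
        spec.density = spec.density / spec.norm()
        assert y_star(spec, y0) <= y_star(spec, y0 * 1.5) + 1e-12

    def test_z_star_unit_conversion(self, geom):
        # y* = 1 keV/um in the 0.282 um domain -> 0.6412 Gy
        spec = LinealSpectrum(
            y_edges=np.array([0.995, 1.005]),
            density=np.array([1 / 0.01]),
            component="beta", nuclide="unit", n_samples=0, seed=None,
        )
        expected = KEV_PER_UM3_TO_GY * y_star(spec, geom.y0) / (np.pi * geom.r_d**2)
        assert z_star_1d(spec, geom) == pytest.approx(expected, rel=1e-12)
        assert z_star_1d(spec, geom) == pytest.approx(0.6412, abs=2e-3)

    def test_z_star_quarter_at_double_radius(self):
        spec = LinealSpectrum(
            y_edges=np.array([0.995, 1.005]),
            density=np.array([1 / 0.01]),
            component="beta", nuclide="unit", n_samples=0, seed=None,
        )
        g1 = DomainGeometry(r_d=0.282, y0=1e6)
        g2 = DomainGeometry(r_d=0.564, y0=1e6)
        assert z_star_1d(spec, g2) == pytest.approx(z_star_1d(spec, g1) / 4, rel=1e-9)


class TestMixing:
    def _two_specs(self, geom, at211_inventory, f18):
        edges = default_y_edges()
        sa = compute_dose_pd(at211_inventory, "alpha", geom, 30_000, seed=1, y_edges=edges)
        sb = compute_dose_pd(f18, "beta", geom, 30_000, seed=2, y_edges=edges)
        return sa, sb

    def test_zero_beta_dose_gives_pure_alpha(self, geom, at211_inventory, f18):
        sa, sb = self._two_specs(geom, at211_inventory, f18)
        mix = mix_spectra(sa, sb, 1.0, 0.0)
        assert np.array_equal(mix.density, sa.density)

    def test_equal_identical_inputs_unchanged(self, geom, at211_inventory, f18):
        sa, _ = self._two_specs(geom, at211_inventory, f18)
        mix = mix_spectra(sa, sa, 2.0, 2.0)
        assert np.allclose(mix.density, sa.density)

    def test_disjoint_support_dose_split(self, geom, at211_inventory, f18):
        sa, sb = self._two_specs(geom, at211_inventory, f18)
        mix = mix_spectra(sa, sb, 3.0, 1.0)
        # alpha support (above 20 keV/um) carries ~75% of the dose weight
        w = mix.density * mix.dy
        hi = float(np.sum(w[mix.y_mid > 20]))
        assert hi == pytest.approx(0.75, abs=0.03)
        assert mix.norm() == pytest.approx(1.0, abs=1e-6)

    def test_z_star_mixes_linearly(self, geom, at211_inventory, f18):
        # Eq-3 integral is linear in d(y): z* of the mixture equals the
        # dose-weighted combination of component z* values
        sa, sb = self._two_specs(geom, at211_inventory, f18)
        da, db = 5.0, 2.0
        mix = mix_spectra(sa, sb, da, db)
        expected = (da * z_star_1d(sa, geom) + db * z_star_1d(sb, geom)) / (da + db)
        assert z_star_1d(mix, geom) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_and_mismatched_inputs(self, geom, at211_inventory, f18):
        sa, sb = self._two_specs(geom, at211_inventory, f18)
        with pytest.raises(ValueError, match="degenerate"):
            mix_spectra(sa, sb, 0.0, 0.0)
        other = compute_dose_pd(f18, "beta", geom, 1000, seed=3,
                                y_edges=np.geomspace(0.1, 100, 11))
        with pytest.raises(ValueError, match="grid"):
            mix_spectra(sa, other, 1.0, 1.0)


def test_reference_spectrum_is_low_let(geom):
    ref = reference_electron_spectrum(geom, n_samples=30_000, seed=12)
    assert ref.norm() == pytest.approx(1.0, abs=1e-6)
    # 300 keV electrons: z* of order 1 Gy, far below alpha values
    assert 0.2 < z_star_1d(ref, geom) < 3.0


def test_spectrum_csv_roundtrip(tmp_path, geom, f18):
    spec = compute_dose_pd(f18, "beta", geom, 5000, seed=1)
    out = tmp_path / "spec.csv"
    spec.to_csv(out)
    assert out.exists() and out.with_suffix(".csv.json").exists()
    data = np.loadtxt(out, delimiter=",", skiprows=1)
    assert np.allclose(data[:, 1], spec.density, rtol=1e-6)
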