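"""Sphere form factor, polydispersity, Guinier analyses, curve reduction."""

import numpy as np
import pytest
from scipy import optimize

from magnetoferm import saxs
from magnetoferm.saxs import (
    FIRST_SPHERE_ZERO,
    SAXSCurve,
    core_diameter,
    disc_form_factor,
    disc_guinier,
    find_first_minimum,
    first_minimum_radius,
    fit_sphere,
    guinier_fit,
    polydisperse_intensity,
    radius_from_rg,
    reduce_curve,
    sphere_form_factor,
    synth_curve,
)


def _tan_roots(n):
    """Oracle: first n positive roots of tan(x) = x by bracketed bisection."""
    roots = []
    for k in range(1, n + 1):
        lo = k * np.pi + 1e-9
        hi = (k + 0.5) * np.pi - 1e-9
        roots.append(optimize.brentq(lambda x: np.tan(x) - x, lo, hi, xtol=1e-12))
    return roots


class TestSphereFormFactor:
    def test_normalized_at_zero(self):
        assert sphere_form_factor(0.0, 100.0) == pytest.approx(1.0)
        assert sphere_form_factor(1e-9, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_zeros_at_tan_roots_vs_oracle(self):
        for x in _tan_roots(3):
            assert sphere_form_factor(x, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_first_zero_constant_matches_oracle(self):
        assert FIRST_SPHERE_ZERO == pytest.approx(_tan_roots(1)[0], abs=1e-9)

    def test_value_at_pi(self):
        assert sphere_form_factor(np.pi, 1.0) == pytest.approx((3 / np.pi**2) ** 2, rel=1e-12)

    def test_bounded_in_unit_interval(self):
        q = np.linspace(0, 2, 5000)
        p = sphere_form_factor(q, 10.0)
        assert np.all(p >= 0) and np.all(p <= 1 + 1e-12)

    def test_rejects_non_positive_radius(self):
        with pytest.raises(ValueError):
            sphere_form_factor(0.1, 0.0)


class TestPolydisperseIntensity:
    def test_sd_zero_is_monodisperse(self):
        q = np.geomspace(0.005, 0.2, 100)
        a = polydisperse_intensity(q, 30.0, 0.0, scale=2.0, background=0.5)
        b = 2.0 * sphere_form_factor(q, 150.0) + 0.5
        assert a == pytest.approx(b, rel=1e-12)

    def test_small_sd_converges_to_monodisperse(self):
        q = np.geomspace(0.005, 0.2, 100)
        mono = polydisperse_intensity(q, 30.0, 0.0)
        near = polydisperse_intensity(q, 30.0, 1e-4, n_nodes=201)
        assert np.max(np.abs(near - mono) / np.maximum(mono, 1e-300)) < 1e-4

    def test_polydispersity_fills_the_first_minimum(self):
        q = np.geomspace(0.01, 0.1, 400)
        sharp = polydisperse_intensity(q, 39.0, 0.0)
        smeared = polydisperse_intensity(q, 39.0, 3.9)
        window = (q > 0.02) & (q < 0.03)
        assert smeared[window].min() / smeared[window].max() > sharp[window].min() / sharp[window].max()

    def test_warns_on_heavy_truncation(self):
        with pytest.warns(UserWarning, match="truncated"):
            polydisperse_intensity(np.array([0.01]), 10.0, 9.0)

    def test_smeared_first_minimum_near_printed_location(self):
        q = np.geomspace(0.005, 0.1, 400)
        c = synth_curve(q, "sphere", mean_diameter_nm=39.0, sd_nm=7.0)
        qmin = find_first_minimum(c.q, c.intensity)
        assert qmin is not None and 0.02 <= qmin <= 0.04


class TestSphereFit:
    def test_round_trip_recovery_39_7(self):
        q = np.geomspace(0.004, 0.25, 300)
        c = synth_curve(q, "sphere", mean_diameter_nm=39.0, sd_nm=7.0,
                        scale=1e4, background=2.0, noise_fraction=0.02,
                        noise_floor=1e-3, seed=3)
        fit = fit_sphere(c)
        assert fit.diameter_nm == pytest.approx(39.0, rel=0.02)
        assert fit.sd_nm == pytest.approx(7.0, rel=0.05)

    def test_scale_invariance(self):
        q = np.geomspace(0.004, 0.25, 200)
        c1 = synth_curve(q, "sphere", mean_diameter_nm=34.0, sd_nm=7.0, scale=1.0)
        c2 = synth_curve(q, "sphere", mean_diameter_nm=34.0, sd_nm=7.0, scale=1e6)
        f1 = fit_sphere(c1, fit_background=False)
        f2 = fit_sphere(c2, fit_background=False)
        assert f1.diameter_nm == pytest.approx(f2.diameter_nm, rel=1e-4)


class TestFirstMinimum:
    def test_radius_division(self):
        assert first_minimum_radius(0.0449341) == pytest.approx(100.0, rel=1e-4)

    def test_printed_q_gives_30nm_scale(self):
        assert 2 * first_minimum_radius(0.03) / 10 == pytest.approx(29.96, abs=0.01)

    def test_inverse_proportionality(self):
        assert first_minimum_radius(0.01) == pytest.approx(2 * first_minimum_radius(0.02))


class TestGuinier:
    def test_round_trip_sphere_radius(self):
        radius = 10.0  # Angstrom
        rg = np.sqrt(3 / 5) * radius
        q = np.linspace(0.005, 1.25 / rg, 80)
        c = synth_curve(q, "sphere", mean_diameter_nm=2 * radius / 10, sd_nm=0.0)
        g = guinier_fit(c, (q[0], q[-1]))
        assert g.valid
        assert g.sphere_radius_nm * 10 == pytest.approx(radius, rel=0.02)

    def test_flat_curve_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        c = SAXSCurve(q, np.ones_like(q))
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(c, (0.01, 0.1))

    def test_membrane_scale_subunit(self):
        # a 3.35 nm monodisperse envelope subunit has Rg ~ 1.3 nm
        radius_nm = 3.35 / 2
        rg_nm = np.sqrt(3 / 5) * radius_nm
        assert rg_nm == pytest.approx(1.30, abs=0.01)
        q = np.linspace(0.005, 1.2 / (rg_nm * 10), 60)
        c = synth_curve(q, "sphere", mean_diameter_nm=3.35, sd_nm=0.0)
        g = guinier_fit(c, (q[0], q[-1]))
        assert g.rg_nm == pytest.approx(rg_nm, rel=0.02)

    def test_validity_flag_post_hoc(self):
        radius = 20.0
        rg = np.sqrt(3 / 5) * radius
        q = np.linspace(0.005, 2.5 / rg, 80)
        c = synth_curve(q, "sphere", mean_diameter_nm=2 * radius / 10, sd_nm=0.0)
        g = guinier_fit(c, (q[0], q[-1]))
        assert not g.valid

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.02, 3)
        c = SAXSCurve(q, np.exp(-q**2 * 100))
        with pytest.raises(ValueError, match=">= 5"):
            guinier_fit(c, (0.01, 0.02))


class TestRadiusFromRg:
    def test_membrane_value(self):
        assert radius_from_rg(1.3) == pytest.approx(1.678, abs=0.001)
        assert round(radius_from_rg(1.3), 1) == 1.7

    def test_inverse_relation(self):
        assert radius_from_rg(np.sqrt(3 / 5)) == pytest.approx(1.0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            radius_from_rg(0.0)


class TestCoreDiameter:
    @pytest.mark.parametrize("overall, core", [(39.0, 35.6), (34.0, 30.6)])
    def test_membrane_subtraction(self, overall, core):
        assert core_diameter(overall, 1.7) == pytest.approx(core)

    def test_zero_membrane_identity(self):
        assert core_diameter(10.0, 0.0) == 10.0

    def test_rejects_non_physical(self):
        with pytest.raises(ValueError, match="non-physical"):
            core_diameter(3.0, 1.7)


class TestReduceCurve:
    def _curve(self, q, i, time, thick, trans, sigma=None):
        return SAXSCurve(q, i, sigma, {"accumulation_time": time, "thickness": thick,
                                       "transmission": trans})

    def test_self_subtraction_vanishes(self):
        q = np.geomspace(0.005, 0.2, 50)
        i = 100 * np.exp(-(q * 50) ** 2 / 3) + 1.0
        buf = self._curve(q, i, 1.0, 1.0, 1.0, sigma=0.01 * i)
        red = reduce_curve(buf, buf)
        assert np.all(np.abs(red.intensity) <= red.sigma + 1e-12)

    def test_normalization_removes_accumulation_time(self):
        q = np.geomspace(0.005, 0.2, 50)
        i = 10 * sphere_form_factor(q, 100.0) + 0.2
        ib = np.full_like(q, 0.2)
        a = reduce_curve(self._curve(q, i, 1.0, 1.0, 1.0), self._curve(q, ib, 1.0, 1.0, 1.0))
        b = reduce_curve(self._curve(q, 2 * i, 2.0, 1.0, 1.0), self._curve(q, ib, 1.0, 1.0, 1.0))
        assert a.intensity == pytest.approx(b.intensity)

    def test_round_trip_with_synthetic_buffer(self):
        q = np.geomspace(0.005, 0.2, 120)
        model = polydisperse_intensity(q, 39.0, 7.0, scale=50.0)
        sample = self._curve(q, model + 0.8, 1.0, 1.0, 1.0)
        buffer = self._curve(q, np.full_like(q, 0.8), 1.0, 1.0, 1.0)
        red = reduce_curve(sample, buffer)
        assert red.intensity == pytest.approx(model, rel=1e-9)

    def test_linearity(self):
        q = np.geomspace(0.005, 0.2, 40)
        ia = np.exp(-q * 10)
        ib = np.exp(-q * 5)
        buf = self._curve(q, np.full_like(q, 0.1), 1.0, 1.0, 1.0)
        ra = reduce_curve(self._curve(q, ia, 1.0, 1.0, 1.0), buf)
        rb = reduce_curve(self._curve(q, ib, 1.0, 1.0, 1.0), buf)
        rab = reduce_curve(self._curve(q, ia + ib, 1.0, 1.0, 1.0), buf)
        assert rab.intensity == pytest.approx(ra.intensity + rb.intensity + 0.1, rel=1e-9)

    def test_rejects_insufficient_overlap(self):
        q = np.geomspace(0.005, 0.2, 40)
        s = self._curve(q, np.ones_like(q), 1.0, 1.0, 1.0)
        b = self._curve(q[10:], np.ones_like(q[10:]), 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="range"):
            reduce_curve(s, b)


class TestDiscGuinier:
    def test_flake_round_trip(self):
        q = np.geomspace(0.004, 0.15, 250)
        c = synth_curve(q, "disc", radius_nm=10.0, thickness_nm=3.5)
        res = disc_guinier(c)
        assert res.radius_nm == pytest.approx(10.0, abs=1.0)
        assert res.thickness_nm == pytest.approx(3.5, abs=0.4)
        assert res.flake_like

    def test_sphere_input_not_flake_like(self):
        q = np.geomspace(0.004, 0.15, 250)
        c = synth_curve(q, "sphere", mean_diameter_nm=20.0, sd_nm=0.0)
        res = disc_guinier(c)
        assert not res.flake_like

    def test_zero_thickness_generator_rejected(self):
        q = np.geomspace(0.004, 0.15, 50)
        with pytest.raises(ValueError):
            disc_form_factor(q, 100.0, 0.0)

    def test_narrow_window_rejected(self):
        q = np.geomspace(0.004, 0.006, 12)
        c = synth_curve(q, "disc", radius_nm=10.0, thickness_nm=3.5)
        with pytest.raises(ValueError):
            disc_guinier(c, thickness_window=(0.10, 0.12))


class TestSynthCurve:
    def test_noiseless_equals_model(self):
        q = np.geomspace(0.005, 0.2, 60)
        c = synth_curve(q, "sphere", mean_diameter_nm=39.0, sd_nm=7.0, scale=3.0, background=0.1)
        assert c.intensity == pytest.approx(polydisperse_intensity(q, 39.0, 7.0, 3.0, 0.1))
        assert np.all(c.sigma == 0)

    def test_two_seeds_same_model_different_noise(self):
        q = np.geomspace(0.005, 0.2, 60)
        c1 = synth_curve(q, "sphere", noise_fraction=0.05, seed=1)
        c2 = synth_curve(q, "sphere", noise_fraction=0.05, seed=2)
        assert not np.array_equal(c1.intensity, c2.intensity)
        assert np.array_equal(c1.sigma, c2.sigma)  # truthful, model-based sigma
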