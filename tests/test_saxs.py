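"""Scattering forward models, the Debye oracle and parameter recovery."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pgk.assembly import ScatteringProfile, SphereAssembly
from pgk.saxs import (SAXSModelParams, debye_intensity, default_q_grid,
                      fit_saxs, model_intensity, py_structure_factor,
                      sphere_form_factor, sticky_hs_structure_factor,
                      synthetic_profile)


class TestSphereFormFactor:
    def test_normalised_at_zero(self):
        assert sphere_form_factor(np.array([0.0]), 105.0)[0] == 1.0

    def test_first_zero_location(self):
        # root of tan x = x
        x0 = brentq(lambda x: np.sin(x) - x * np.cos(x), 3.0, 6.0)
        R = 105.0
        q = np.array([x0 / R])
        assert sphere_form_factor(q, R)[0] < 1e-12

    def test_guinier_low_q_limit(self):
        R = 105.0
        rg2 = 3.0 / 5.0 * R ** 2
        q = np.linspace(1e-4, 0.5 / np.sqrt(rg2), 50)
        P = sphere_form_factor(q, R)
        guinier = np.exp(-q ** 2 * rg2 / 3.0)
        assert np.all(np.abs(P - guinier) / guinier < 0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sphere_form_factor(np.array([0.1]), -1.0)
        with pytest.raises(ValueError):
            sphere_form_factor(np.array([-0.1]), 10.0)


class TestPyStructureFactor:
    def test_ideal_gas_limit(self):
        q = default_q_grid()
        assert np.allclose(py_structure_factor(q, 109.0, 0.0), 1.0)

    def test_compressibility_at_zero_q(self):
        phi = 0.49
        s0 = py_structure_factor(np.array([1e-8]), 109.0, phi)[0]
        assert s0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2,
                                   rel=1e-6)

    def test_high_q_approaches_one(self):
        s = py_structure_factor(np.array([2.0]), 109.0, 0.49)  # q r_hs > 100
        assert abs(s[0] - 1.0) < 1e-3

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            py_structure_factor(np.array([0.1]), 109.0, 0.8)


class TestStickyStructureFactor:
    def test_large_tau_recovers_py(self):
        q = default_q_grid()
        s_py = py_structure_factor(q, 109.0, 0.3)
        s_shs = sticky_hs_structure_factor(q, 109.0, 0.3, 1e6)
        assert np.max(np.abs(s_py - s_shs)) < 1e-3

    def test_zero_q_compressibility_grows_with_stickiness(self):
        q = np.array([1e-8])
        s0 = [sticky_hs_structure_factor(q, 109.0, 0.3, tau)[0]
              for tau in (10.0, 1.0, 0.3)]
        assert s0[0] < s0[1] < s0[2]

    def test_phi_zero_is_unity(self):
        q = default_q_grid()
        assert np.allclose(sticky_hs_structure_factor(q, 109.0, 0.0, 0.5), 1.0)

    def test_unphysical_region_raises(self):
        # phi = 0.2, tau = 0.01: the Baxter quadratic has no real root
        with pytest.raises(ValueError, match="Baxter"):
            sticky_hs_structure_factor(default_q_grid(), 109.0, 0.2, 0.01)


class TestModelIntensity:
    def test_dilute_monodisperse_reduces_to_form_factor(self):
        q = default_q_grid()
        p = SAXSModelParams(d_mean=218.0, d_sd=0.0, phi=0.0, scale=2.5,
                            background=0.1)
        I = model_intensity(q, p)
        np.testing.assert_allclose(
            I, 2.5 * sphere_form_factor(q, 109.0) + 0.1, rtol=1e-12)

    def test_polydispersity_damps_minima(self):
        q = default_q_grid(400)
        sharp = model_intensity(q, SAXSModelParams(218.0, 0.0, 0.0))
        soft = model_intensity(q, SAXSModelParams(218.0, 21.8, 0.0))
        # depth of the first form-factor minimum (around q R ~ 4.49)
        window = (q > 0.035) & (q < 0.05)
        assert soft[window].min() / max(sharp[window].min(), 1e-30) > 5.0

    def test_structure_peak_near_mean_spacing(self):
        q = np.linspace(0.01, 0.08, 2000)
        p = SAXSModelParams(d_mean=218.0, d_sd=0.0, phi=0.5)
        I = model_intensity(q, p)
        q_star = q[np.argmax(py_structure_factor(q, 109.0, 0.5))]
        spacing = 2 * np.pi / q_star
        assert abs(spacing - 218.0) / 218.0 < 0.15

    def test_py_equals_sticky_infinite_tau(self):
        q = default_q_grid()
        p1 = SAXSModelParams(218.0, 21.8, 0.49)
        p2 = SAXSModelParams(218.0, 21.8, 0.49, tau=1e6)
        np.testing.assert_allclose(model_intensity(q, p1, "py"),
                                   model_intensity(q, p2, "sticky"),
                                   rtol=2e-3)


class TestDebyeIntensity:
    def test_single_sphere_proportional_to_form_factor(self):
        a = SphereAssembly([[500.0, 500, 500]], [105.0], [1000.0] * 3,
                           [False] * 3)
        q = default_q_grid(50)
        I = debye_intensity(a, q)
        P = sphere_form_factor(q, 105.0)
        ratio = I / P
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_two_spheres_closed_form(self):
        D = 300.0
        R = 105.0
        a = SphereAssembly([[500.0, 500, 350], [500.0, 500, 650]],
                           [R, R], [1000.0] * 3, [False] * 3)
        q = default_q_grid(40)
        I = debye_intensity(a, q)
        V = 4 / 3 * np.pi * R ** 3
        x = q * R
        F = V * 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
        expected = 2 * F ** 2 * (1 + np.sin(q * D) / (q * D))
        np.testing.assert_allclose(I, expected, rtol=1e-10)

    def test_structure_peak_matches_py_model(self, small_jammed_packing):
        """Debye sum from a jammed packing peaks where PY says it should."""
        a = small_jammed_packing
        d = 2 * a.radii.mean()
        q = np.linspace(2.0 / d, 12.0 / d, 300)
        I = debye_intensity(a, q)
        P = sphere_form_factor(q, float(a.radii.mean()))
        S_eff = I / (a.n * P * (4 / 3 * np.pi * a.radii.mean() ** 3) ** 2)
        S_py = py_structure_factor(q, float(a.radii.mean()),
                                   float(a.meta["phi"]))
        # compare the main (nearest-neighbour) peak; the lowest-q region of
        # the finite periodic box carries minimum-image artifacts
        window = (q > 4.5 / d) & (q < 9.0 / d)
        q_star = q[window][np.argmax(S_eff[window])]
        q_py = q[window][np.argmax(S_py[window])]
        assert abs(q_star - q_py) / q_py < 0.1

    def test_cap_enforced(self, rng):
        n = 30
        a = SphereAssembly(rng.uniform(100, 900, (n, 3)),
                           np.full(n, 10.0), [1000.0] * 3, [False] * 3)
        with pytest.raises(ValueError, match="cap"):
            debye_intensity(a, default_q_grid(10), n_cap=10)


class TestFitSaxs:
    def test_noise_free_self_consistency(self):
        true = SAXSModelParams(218.0, 21.8, 0.49, scale=3.0, background=1e-3)
        prof = synthetic_profile(true, noise=0.0)
        fitted, unc, redchi = fit_saxs(prof, "py", true)
        assert redchi < 1e-6
        assert fitted.d_mean == pytest.approx(218.0, rel=1e-3)

    @pytest.mark.parametrize("d,phi", [(210.0, 0.46), (254.0, 0.53)])
    def test_round_trip_recovery(self, d, phi):
        """Known-parameter synthetic profiles are recovered within 5%."""
        true = SAXSModelParams(d_mean=d, d_sd=0.1 * d, phi=phi, scale=1.0,
                               background=1e-4)
        prof = synthetic_profile(true, noise=0.02,
                                 rng=np.random.default_rng(42))
        init = SAXSModelParams(d_mean=d * 1.2, d_sd=0.05 * d, phi=0.4,
                               scale=0.5, background=1e-4)
        fitted, _, _ = fit_saxs(prof, "py", init)
        assert abs(fitted.d_mean - d) / d < 0.05
        assert abs(fitted.phi - phi) / phi < 0.05
        assert abs(fitted.d_sd - true.d_sd) / true.d_sd < 0.20

    def test_sticky_fit_on_py_data_drives_tau_large(self):
        """Model nesting: pure hard-sphere data needs no stickiness."""
        true = SAXSModelParams(218.0, 21.8, 0.49, scale=1.0, background=1e-4)
        prof = synthetic_profile(true, "py", noise=0.01,
                                 rng=np.random.default_rng(7))
        init = SAXSModelParams(d_mean=230.0, d_sd=20.0, phi=0.45, tau=0.5,
                               scale=0.8, background=1e-4)
        fitted, _, _ = fit_saxs(prof, "sticky", init)
        assert fitted.tau > 50.0
        assert abs(fitted.d_mean - 218.0) / 218.0 < 0.05
        assert abs(fitted.phi - 0.49) / 0.49 < 0.05

    def test_too_few_points_rejected(self):
        prof = ScatteringProfile(np.linspace(0.01, 0.1, 5), np.ones(5))
        with pytest.raises(ValueError, match="10 data points"):
            fit_saxs(prof, "py", SAXSModelParams(218.0))
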