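"""SAXS reductions against closed-form and independent-quadrature oracles."""

import numpy as np
import pytest
from scipy import integrate, special

import oligostate.saxs as saxs
from oligostate.saxs import (GuinierRegionError, RodRegimeError,
                             ScatteringProfile, cross_section_guinier,
                             cylinder_intensity, dimensionless_kratky,
                             elliptical_cylinder_intensity, fit_form_factor,
                             guinier_fit, ift, model_rg, scan_dmax,
                             volume_to_mw)
from oligostate.synthetic import SaxsSimSpec, simulate_saxs


class TestGuinier:
    def test_exact_on_ideal_scatterer(self, guinier_profile):
        fit = guinier_fit(guinier_profile)
        assert fit.rg == pytest.approx(60.0, abs=1e-6)
        assert fit.i0 == pytest.approx(1.0, abs=1e-9)

    def test_sphere_rg_closed_form(self, sphere_profile_clean):
        # the finite qRg <= 1.3 window overestimates a sphere's Rg by ~2%
        # (known truncation bias of the Guinier approximation); the exact
        # closed form sqrt(3/5) R is recovered by the IFT route instead
        fit = guinier_fit(sphere_profile_clean)
        assert fit.rg == pytest.approx(30.0 * np.sqrt(3.0 / 5.0), rel=0.02)

    def test_window_respects_qrg_limit(self, sphere_profile_clean):
        fit = guinier_fit(sphere_profile_clean, qrg_limit=1.3)
        assert fit.qrg_max <= 1.3 + 1e-9

    def test_increasing_low_q_raises(self):
        q = np.linspace(0.005, 0.1, 60)
        prof = ScatteringProfile(q, np.exp(+q**2 * 500.0))
        with pytest.raises(GuinierRegionError):
            guinier_fit(prof)

    def test_too_few_points_raises(self):
        q = np.linspace(0.01, 0.02, 3)
        with pytest.raises(ValueError):
            guinier_fit(ScatteringProfile(q, np.exp(-q**2 * 1200.0)))


class TestCrossSection:
    def test_exact_inversion_of_rod_regime(self):
        q = np.linspace(0.02, 0.25, 120)
        rc = 5.0
        prof = ScatteringProfile(q, (1.0 / q) * np.exp(-q**2 * rc**2 / 2.0))
        fit = cross_section_guinier(prof, window=(0.02, 0.25))
        assert fit.rc == pytest.approx(5.0, abs=1e-9)

    def test_rod_diameter_formula(self):
        q = np.linspace(0.02, 0.25, 120)
        prof = ScatteringProfile(q, (1.0 / q) * np.exp(-q**2 * 4.86**2 / 2.0))
        fit = cross_section_guinier(prof, window=(0.02, 0.25))
        assert round(fit.diameter, 1) == 13.7

    def test_tiny_rc_diameter_is_sqrt2(self):
        # diameter formula alone: 2 * 0.5 * sqrt(2)
        from oligostate.saxs import CrossSectionFit
        fit = CrossSectionFit(rc=0.5, rc_sd=0.0, q_min=0, q_max=1, n_points=0)
        assert fit.diameter == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_flat_data_raises(self):
        q = np.linspace(0.02, 0.2, 60)
        with pytest.raises(RodRegimeError):
            cross_section_guinier(ScatteringProfile(q, np.ones_like(q) / q * np.exp(q**2)),
                                  window=(0.02, 0.2))


class TestKratky:
    def test_ideal_scatterer_peaks_at_reference_point(self, guinier_profile):
        fit = guinier_fit(guinier_profile)
        k = dimensionless_kratky(guinier_profile, fit)
        assert k.peak_x == pytest.approx(np.sqrt(3.0), abs=2e-3)
        assert k.peak_y == pytest.approx(3.0 / np.e, abs=1e-3)

    def test_reference_point_independent_of_rg(self):
        for rg in (25.0, 90.0):
            q = np.linspace(0.2 / rg, 6.0 / rg, 500)
            prof = simulate_saxs(SaxsSimSpec("guinier", {"rg": rg}, q,
                                             frac_sd=0.0))
            fit = guinier_fit(prof)
            k = dimensionless_kratky(prof, fit)
            assert k.peak_y == pytest.approx(1.104, abs=1e-3)

    def test_flat_profile_has_no_interior_peak(self):
        q = np.linspace(0.01, 0.3, 50)
        prof = ScatteringProfile(q, np.ones_like(q))
        fit = saxs.GuinierFit(rg=60.0, i0=1.0, q_min=0, q_max=0, qrg_max=0,
                              rg_sd=0, n_points=0)
        k = dimensionless_kratky(prof, fit)
        assert np.all(np.diff(k.y) > 0)
        assert k.peak_x is None

    def test_scale_invariance(self, guinier_profile):
        fit = guinier_fit(guinier_profile)
        k1 = dimensionless_kratky(guinier_profile, fit)
        doubled = ScatteringProfile(guinier_profile.q, 2.0 * guinier_profile.I)
        fit2 = saxs.GuinierFit(rg=fit.rg, i0=2.0 * fit.i0, q_min=fit.q_min,
                               q_max=fit.q_max, qrg_max=fit.qrg_max,
                               rg_sd=fit.rg_sd, n_points=fit.n_points)
        k2 = dimensionless_kratky(doubled, fit2)
        np.testing.assert_allclose(k1.y, k2.y, rtol=1e-12)


class TestIft:
    def test_sphere_pr_closed_form(self, sphere_profile_clean):
        dist = ift(sphere_profile_clean, 60.0)
        R = 30.0
        r = dist.r
        oracle = r**2 * (1 - 3 * r / (4 * R) + r**3 / (16 * R**3))
        pn = dist.p / dist.p.max()
        on = oracle / oracle.max()
        rms = np.sqrt(np.mean((pn - on) ** 2))
        assert rms < 0.02
        assert dist.rg == pytest.approx(23.24, abs=0.3)

    def test_endpoints_are_zero_and_integral_positive(self, sphere_profile_clean):
        dist = ift(sphere_profile_clean, 60.0)
        assert dist.p[0] == 0.0 and dist.p[-1] == 0.0
        assert np.trapezoid(dist.p, dist.r) > 0

    def test_negativity_penalty_keeps_p_nearly_nonnegative(self,
                                                           sphere_profile_noisy):
        dist = ift(sphere_profile_noisy, 60.0)
        assert dist.p.min() >= -0.01 * dist.p.max()

    def test_back_transform_chi2_on_noisy_data(self, sphere_profile_noisy):
        dist = ift(sphere_profile_noisy, 60.0)
        pred = dist.back_transform(sphere_profile_noisy.q)
        chi2 = np.mean(((pred - sphere_profile_noisy.I)
                        / sphere_profile_noisy.sigma_eff) ** 2)
        assert chi2 <= 1.5

    def test_real_space_rg_definition_holds(self, sphere_profile_clean):
        dist = ift(sphere_profile_clean, 60.0)
        rg2 = np.trapezoid(dist.r**2 * dist.p, dist.r) \
            / (2 * np.trapezoid(dist.p, dist.r))
        assert dist.rg == pytest.approx(np.sqrt(rg2), rel=1e-12)

    def test_elliptical_cylinder_rg_recovered(self):
        q = np.linspace(0.005, 0.35, 240)
        prof = simulate_saxs(SaxsSimSpec(
            "elliptical_cylinder", {"a": 77.0, "nu": 1.2, "length": 16.0},
            q, frac_sd=0.0))
        dist = ift(prof, 200.0)
        target = model_rg("elliptical_cylinder",
                          {"a": 77.0, "nu": 1.2, "length": 16.0})
        assert dist.rg == pytest.approx(target, rel=0.02)

    def test_dmax_below_resolution_warns(self, sphere_profile_clean):
        with pytest.warns(UserWarning, match="resolution"):
            ift(sphere_profile_clean, 5.0)


class TestScanDmax:
    def test_sphere_selects_true_diameter(self, sphere_profile_noisy):
        best, scores = scan_dmax(sphere_profile_noisy,
                                 [40, 50, 60, 70, 80, 90, 100])
        assert 55 <= best <= 70

    def test_truncated_supports_score_worse(self, sphere_profile_clean):
        _, scores = scan_dmax(sphere_profile_clean, [20, 30, 40, 55])
        vals = [scores[d] for d in (20, 30, 40, 55)]
        assert vals == sorted(vals)

    def test_single_candidate_returned(self, sphere_profile_clean):
        best, scores = scan_dmax(sphere_profile_clean, [60.0])
        assert best == 60.0 and set(scores) == {60.0}


class TestFormFactors:
    def test_elliptical_reduces_to_circular_cylinder(self):
        # independent oracle: adaptive quadrature of the standard cylinder
        # orientation average
        q = np.linspace(0.005, 0.5, 25)
        R, L = 30.0, 100.0

        def oracle(qi):
            def f(alpha):
                u = qi * R * np.sin(alpha)
                rod = np.sinc(qi * L * np.cos(alpha) / 2.0 / np.pi)
                bessel = 2.0 * special.j1(u) / u if u > 0 else 1.0
                return (bessel * rod) ** 2 * np.sin(alpha)
            val, _ = integrate.quad(f, 0.0, np.pi / 2.0, limit=200)
            return val

        ours = elliptical_cylinder_intensity(q, R, 1.0, L, order=76)
        ref = np.array([oracle(qi) for qi in q])
        np.testing.assert_allclose(ours, ref, rtol=1e-6)

    def test_forward_scattering_normalised(self):
        val = elliptical_cylinder_intensity(np.array([1e-7]), 77, 1.2, 16)[0]
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_quadrature_self_convergence(self):
        q = np.linspace(0.005, 0.5, 60)
        lo = elliptical_cylinder_intensity(q, 77, 1.2, 16, order=76)
        hi = elliptical_cylinder_intensity(q, 77, 1.2, 16, order=152)
        assert np.max(np.abs(lo - hi) / hi) < 1e-6


class TestFormFactorFit:
    def test_noise_free_self_consistency(self):
        q = np.geomspace(0.006, 0.3, 120)
        prof = simulate_saxs(SaxsSimSpec(
            "elliptical_cylinder", {"a": 77.0, "nu": 1.2, "length": 16.0},
            q, frac_sd=0.0))
        fit = fit_form_factor(prof, "elliptical_cylinder",
                              fixed={"length": 16.0},
                              bounds={"a": (20, 200), "nu": (1, 2.5)})
        assert fit.params["a"] == pytest.approx(77.0, rel=5e-3)
        assert fit.params["nu"] == pytest.approx(1.2, rel=5e-3)

    def test_parameter_recovery_at_two_percent_noise(self):
        q = np.geomspace(0.006, 0.3, 120)
        prof = simulate_saxs(SaxsSimSpec(
            "elliptical_cylinder", {"a": 77.0, "nu": 1.2, "length": 16.0},
            q, frac_sd=0.02, seed=11))
        fit = fit_form_factor(prof, "elliptical_cylinder",
                              fixed={"length": 16.0},
                              bounds={"a": (20, 200), "nu": (1, 2.5)})
        assert fit.params["a"] == pytest.approx(77.0, rel=0.05)
        assert fit.params["nu"] == pytest.approx(1.2, rel=0.05)
        assert 0.5 <= fit.chi2_red <= 2.0

    def test_reported_chi2_reproducible_from_parameters(self):
        q = np.geomspace(0.006, 0.3, 80)
        prof = simulate_saxs(SaxsSimSpec("sphere", {"radius": 30.0}, q,
                                         frac_sd=0.02, seed=4))
        fit = fit_form_factor(prof, "sphere", bounds={"radius": (5, 100)})
        imod = saxs.sphere_intensity(q, fit.params["radius"])
        chi2 = np.sum(((fit.scale * imod + fit.background - prof.I)
                       / prof.sigma_eff) ** 2)
        assert chi2 / (len(q) - 3) == pytest.approx(fit.chi2_red, rel=1e-9)


class TestModelRgAndMw:
    @pytest.mark.parametrize("model,params,expected", [
        ("sphere", {"radius": 30.0}, 30.0 * np.sqrt(3.0 / 5.0)),
        ("elliptical_cylinder", {"a": 77.0, "nu": 1.2, "length": 16.0}, 60.316),
    ])
    def test_closed_forms(self, model, params, expected):
        assert model_rg(model, params) == pytest.approx(expected, abs=5e-3)

    def test_thin_disk_limit(self):
        # L -> 0, a = b = R gives sqrt(R^2/2)
        rg = model_rg("elliptical_cylinder",
                      {"a": 40.0, "nu": 1.0, "length": 1e-9})
        assert rg == pytest.approx(np.sqrt(40.0**2 / 2.0), rel=1e-6)

    def test_unknown_model_raises(self):
        with pytest.raises(ValueError):
            model_rg("pyramid", {})

    def test_volume_to_mw_reference_value(self):
        est = volume_to_mw(105.0, vbar=0.73)
        assert est.mw_kda == pytest.approx(86.6, abs=0.1)
        assert est.divisor_nm3_per_kda == pytest.approx(1.212, abs=0.002)

    def test_volume_to_mw_unit_case_and_linearity(self):
        assert volume_to_mw(1.212).mw_kda == pytest.approx(1.0, abs=2e-3)
        assert volume_to_mw(50.0).mw_kda == pytest.approx(
            2 * volume_to_mw(25.0).mw_kda, rel=1e-12)


class TestCrossMethodConsistency:
    def test_guinier_and_ift_agree_on_rg(self, sphere_profile_clean):
        g = guinier_fit(sphere_profile_clean)
        d = ift(sphere_profile_clean, 60.0)
        assert abs(g.rg - d.rg) / d.rg < 0.03
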