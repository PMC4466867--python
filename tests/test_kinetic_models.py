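"""Forward-model correctness: convolution machinery, closed forms vs
independent oracles, nesting identities and structural properties."""

import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dcefit.aif import AIFCurve, parker_aif
from dcefit.kinetic_models import (
    KineticParams,
    auc_metric,
    convolve_uniform,
    cumulative_integral,
    evaluate_model,
    exp_conv,
    fxr_observed_r1,
    model_2cxm,
    model_extended_tofts,
    model_fxr_signal,
    model_patlak,
    model_steady_state,
    model_tissue_uptake,
    model_tofts,
)
from dcefit.simulation import DEFAULT_ACQUISITION

DT = 0.5 / 60.0


class TestConvolution:
    def test_delta_kernel_is_identity(self, population_aif):
        # a discrete delta at the domain boundary carries half weight under
        # the trapezoid rule, so unit mass needs height 2/dt there
        ca = population_aif.conc
        delta = np.zeros_like(ca)
        delta[0] = 2.0 / DT
        out = convolve_uniform(ca, delta, DT)
        assert np.allclose(out[1:], ca[1:], atol=1e-10)

    def test_matches_direct_quadrature_oracle(self, population_aif):
        ca = population_aif.conc
        kern = np.exp(-1.7 * DT * np.arange(len(ca)))
        out = convolve_uniform(ca, kern, DT)
        for n in (3, 50, 400):
            direct = np.trapezoid(ca[: n + 1] * kern[: n + 1][::-1], dx=DT)
            assert out[n] == pytest.approx(direct, abs=1e-12)

    def test_zero_impulse_gives_zero(self, population_aif):
        out = convolve_uniform(population_aif.conc, np.zeros_like(population_aif.conc), DT)
        assert np.all(out == 0)

    def test_biexponential_closed_form(self, time_grid):
        # gentle washout-scale rates; closed form k A (e^-bt - e^-at)/(a-b)
        a, amp, b, k = 0.2, 5.0, 0.02, 1.3
        f = amp * np.exp(-a * time_grid)
        g = k * np.exp(-b * time_grid)
        expected = k * amp * (np.exp(-b * time_grid) - np.exp(-a * time_grid)) / (a - b)
        out = convolve_uniform(f, g, DT)
        rel = np.max(np.abs(out - expected)) / np.max(expected)
        assert rel < 1e-6

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="non-uniform"):
            model_steady_state(0.1, (t, np.ones_like(t)))

    def test_exp_conv_matches_generic_convolution(self, population_aif):
        """The O(n) exponential recursion agrees with sampled-kernel trapezoid
        quadrature to the quadrature's own discretisation error."""
        ca = population_aif.conc
        for rate in (0.1, 1.0, 5.0):
            kern = np.exp(-rate * DT * np.arange(len(ca)))
            generic = convolve_uniform(ca, kern, DT)
            fast = exp_conv(ca, rate, DT)
            assert np.max(np.abs(generic - fast)) < 5e-4 * max(np.max(generic), 1.0)

    def test_exp_conv_exact_for_linear_input(self):
        # input a(t) = t, kernel e^(-kt): closed form (t - (1-e^-kt)/k)/k
        t = DT * np.arange(600)
        k = 2.5
        expected = (t - (1 - np.exp(-k * t)) / k) / k
        assert np.allclose(exp_conv(t, k, DT), expected, atol=1e-12)

    def test_cumulative_integral_is_trapezoid(self, population_aif):
        ca = population_aif.conc
        expected = np.concatenate([[0.0], np.cumsum(0.5 * (ca[1:] + ca[:-1]) * DT)])
        assert np.allclose(cumulative_integral(ca, DT), expected, atol=1e-12)


class TestSimpleModels:
    def test_steady_state_scales_aif(self, population_aif):
        out = model_steady_state(0.1, population_aif)
        assert np.allclose(out.conc, 0.1 * population_aif.conc)
        assert np.all(model_steady_state(0.0, population_aif).conc == 0)
        assert np.allclose(model_steady_state(1.0, population_aif).conc, population_aif.conc)

    def test_patlak_constant_aif_is_linear_ramp(self):
        t = DT * np.arange(200)
        aif = AIFCurve(t, np.full_like(t, 3.0))
        out = model_patlak(0.2, 0.0, aif)
        assert np.allclose(out.conc, 0.2 * 3.0 * t, atol=1e-12)

    def test_patlak_monotone_for_constant_vascular_term(self):
        t = DT * np.arange(200)
        aif = AIFCurve(t, np.full_like(t, 2.0))
        out = model_patlak(0.1, 0.05, aif)
        assert np.all(np.diff(out.conc) >= 0)

    def test_tofts_monoexp_aif_closed_form(self, time_grid):
        amp, a, kt, ve = 4.0, 0.3, 0.12, 0.3
        kep = kt / ve
        aif = AIFCurve(time_grid, amp * np.exp(-a * time_grid))
        expected = kt * amp * (np.exp(-kep * time_grid) - np.exp(-a * time_grid)) / (a - kep)
        out = model_tofts(kt, ve, aif)
        assert np.max(np.abs(out.conc - expected)) < 1e-6 * np.max(expected)

    def test_tofts_washout_to_zero_with_boxcar_aif(self):
        t = DT * np.arange(1201)
        ca = np.where(t < 1.0, 5.0, 0.0)
        out = model_tofts(0.2, 0.1, (t, ca))
        assert out.conc[-1] < 1e-6 * out.conc.max()

    @pytest.mark.parametrize("model,params,reduced,rparams", [
        ("ex_tofts", dict(ktrans=0.1, ve=0.2, vp=0.0), "tofts", dict(ktrans=0.1, ve=0.2)),
        ("ex_tofts", dict(ktrans=0.0, ve=0.2, vp=0.05), "steady_state", dict(v=0.05)),
        ("patlak", dict(ktrans=0.0, vp=0.05), "steady_state", dict(v=0.05)),
    ])
    def test_nesting_identities_exact(self, population_aif, model, params, reduced, rparams):
        full = evaluate_model(model, params, population_aif).conc
        red = evaluate_model(reduced, rparams, population_aif).conc
        assert np.array_equal(full, red) or np.allclose(full, red, atol=0, rtol=0)


class TestTwoCompartmentExchange:
    def _ode_curve(self, kt, ve, vp, fp, times, ca, t_eval):
        e = kt / fp
        ps = fp * e / (1 - e)

        def rhs(tt, y):
            cav = np.interp(tt, times, ca)
            return [(fp * (cav - y[0]) + ps * (y[1] - y[0])) / vp, ps * (y[0] - y[1]) / ve]

        sol = solve_ivp(rhs, (times[0], times[-1]), [0, 0], t_eval=t_eval,
                        method="LSODA", rtol=1e-8, atol=1e-11)
        return vp * sol.y[0] + ve * sol.y[1]

    def test_closed_form_vs_ode_reference_case(self, time_grid, population_aif):
        """Primary correctness oracle: direct integration of the
        two-compartment ODE pair."""
        kt, ve, vp, fp = 0.1, 0.2, 0.05, 1.0
        cl = model_2cxm(kt, ve, vp, fp, population_aif).conc
        ode = self._ode_curve(kt, ve, vp, fp, time_grid, population_aif.conc, time_grid[::10])
        assert np.max(np.abs(cl[::10] - ode)) < 1e-5

    def test_closed_form_vs_eigendecomposition_grid(self, time_grid, population_aif):
        """The hand-derived eigenrates/weights agree with generic linear
        algebra (numpy eig of the compartment matrix) over the study grid."""
        ca = population_aif.conc
        grid = itertools.product([0.01, 0.1, 0.35], [0.01, 0.1, 0.5],
                                 [0.001, 0.01, 0.1], [0.5, 1.0, 5.0])
        for kt, ve, vp, fp in grid:
            e = kt / fp
            ps = fp * e / (1 - e)
            m = np.array([[-(fp + ps) / vp, ps / vp], [ps / ve, -ps / ve]])
            lam, vec = np.linalg.eig(m)
            coef = np.linalg.solve(vec, [fp / vp, 0.0])
            w = np.array([vp, ve]) @ vec
            oracle = sum(
                w[i] * coef[i] * exp_conv(ca, -lam[i], DT) for i in range(2)
            )
            cl = model_2cxm(kt, ve, vp, fp, population_aif).conc
            assert np.max(np.abs(cl - oracle)) < 1e-9, (kt, ve, vp, fp)

    def test_high_flow_limit_approaches_extended_tofts(self, population_aif):
        kt, ve, vp = 0.1, 0.2, 0.05
        xt = model_extended_tofts(kt, ve, vp, population_aif).conc
        devs = [
            np.max(np.abs(model_2cxm(kt, ve, vp, fp, population_aif).conc - xt))
            for fp in (10.0, 100.0, 1000.0)
        ]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 1e-3

    def test_no_leakage_washes_out(self):
        # finite bolus: intravascular-only tissue curve returns to zero
        t = DT * np.arange(1201)
        ca = np.exp(-0.5 * ((t - 1.0) / 0.1) ** 2)
        out = model_2cxm(0.0, 0.2, 0.05, 1.0, (t, ca)).conc
        assert out[-1] < 1e-6 * out.max()

    def test_extraction_fraction_bound_enforced(self, population_aif):
        with pytest.raises(ValueError, match="ktrans < fp"):
            model_2cxm(1.0, 0.2, 0.05, 0.5, population_aif)


class TestTissueUptake:
    def test_matches_2cxm_infinite_ve_limit(self, population_aif):
        from dcefit.kinetic_models import _two_cxm_rates

        kt, vp, fp = 0.1, 0.05, 1.0
        tu = model_tissue_uptake(kt, vp, fp, population_aif).conc
        ca = population_aif.conc
        kpos, kneg, aw = _two_cxm_rates(kt, 1e4, vp, fp)  # ve -> infinity
        limit = fp * (aw * exp_conv(ca, kpos, DT) + (1 - aw) * exp_conv(ca, kneg, DT))
        assert np.max(np.abs(tu - limit)) < 1e-4

    def test_matches_sampled_kernel_convolution(self, population_aif):
        # the analytic impulse response I(t) = fp[(1-E)e^(-t/Tp) + E],
        # sampled and convolved generically, reproduces the model output
        kt, vp, fp = 0.1, 0.3, 0.5
        e = kt / fp
        ps = fp * e / (1 - e)
        tp = vp / (fp + ps)
        t = population_aif.times_min
        kernel = fp * ((1 - e) * np.exp(-t / tp) + e)
        assert kernel[0] == pytest.approx(fp)  # I(0) = fp
        generic = convolve_uniform(population_aif.conc, kernel, DT)
        out = model_tissue_uptake(kt, vp, fp, population_aif).conc
        assert np.max(np.abs(out - generic)) < 1e-4 * np.max(out)

    def test_mass_balance_intravascular(self):
        # ktrans = 0: integral of C equals vp * integral of a compact bolus
        t = DT * np.arange(2401)
        ca = np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)  # bolus fully inside window
        out = model_tissue_uptake(0.0, 0.05, 1.0, (t, ca)).conc
        assert np.trapezoid(out, t) == pytest.approx(0.05 * np.trapezoid(ca, t), rel=1e-4)


class TestFXR:
    def test_eigenvalue_formula_vs_numeric_eigendecomposition(self, rng):
        """Slow relaxation eigenvalue vs numpy eig of the 2x2 exchange
        matrix for random states."""
        for _ in range(100):
            r1e, r1i = rng.uniform(0.3, 10.0, 2)
            tau_i = rng.uniform(0.05, 5.0)
            p_i = rng.uniform(0.05, 0.95)
            tau_e = tau_i * (1 - p_i) / p_i
            m = np.array([[r1e + 1 / tau_e, -1 / tau_i], [-1 / tau_e, r1i + 1 / tau_i]])
            slow = np.min(np.linalg.eigvals(m).real)
            assert fxr_observed_r1(r1e, r1i, tau_i, p_i) == pytest.approx(slow, abs=1e-10)

    def test_fast_exchange_limit(self, population_aif):
        acq = dict(DEFAULT_ACQUISITION)
        kt, ve = 0.1, 0.2
        fxl = model_fxr_signal(kt, ve, 1e-6, population_aif, acq).conc
        d_small = np.max(np.abs(model_fxr_signal(kt, ve, 1e-4, population_aif, acq).conc - fxl))
        d_big = np.max(np.abs(model_fxr_signal(kt, ve, 1e-2, population_aif, acq).conc - fxl))
        assert d_small < d_big

    def test_no_uptake_gives_flat_baseline_signal(self, population_aif):
        acq = dict(DEFAULT_ACQUISITION)
        out = model_fxr_signal(0.0, 0.2, 0.5, population_aif, acq).conc
        assert np.allclose(out, out[0])

    def test_shutter_speed_attenuates_enhancement(self, population_aif):
        # finite water exchange reduces the apparent R1, hence the signal,
        # relative to the fast-exchange-limit signal at the same kinetics
        from dcefit.kinetic_models import model_tofts
        from dcefit.spgr import spgr_signal

        acq = dict(DEFAULT_ACQUISITION)
        ct = model_tofts(0.2, 0.3, population_aif).conc
        r10 = 1000.0 / acq["t10_ms"]
        fxl = spgr_signal(acq["s0"], r10 + acq["r1"] * ct, acq["fa_deg"], acq["tr_ms"])
        fxr = model_fxr_signal(0.2, 0.3, 2.0, population_aif, acq).conc
        assert np.all(fxr <= fxl + 1e-9)
        assert np.max(fxl - fxr) > 1.0  # the attenuation is substantial


class TestStructuralProperties:
    @pytest.mark.parametrize("model,params", [
        ("patlak", dict(ktrans=0.1, vp=0.02)),
        ("tofts", dict(ktrans=0.1, ve=0.2)),
        ("ex_tofts", dict(ktrans=0.1, ve=0.2, vp=0.02)),
        ("two_cxm", dict(ktrans=0.1, ve=0.2, vp=0.05, fp=1.0)),
        ("tissue_uptake", dict(ktrans=0.1, vp=0.05, fp=1.0)),
    ])
    def test_linearity_in_aif(self, population_aif, model, params):
        base = evaluate_model(model, params, population_aif).conc
        scaled_aif = AIFCurve(population_aif.times_min, 2.5 * population_aif.conc)
        scaled = evaluate_model(model, params, scaled_aif).conc
        assert np.allclose(scaled, 2.5 * base, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("model,params", [
        ("tofts", dict(ktrans=0.35, ve=0.1)),
        ("two_cxm", dict(ktrans=0.2, ve=0.2, vp=0.05, fp=5.0)),
    ])
    def test_grid_refinement_stability(self, model, params):
        t1 = DT * np.arange(1201)
        t2 = (DT / 2) * np.arange(2401)
        c1 = evaluate_model(model, params, parker_aif(t1, onset_min=1.0)).conc
        c2 = evaluate_model(model, params, parker_aif(t2, onset_min=1.0)).conc[::2]
        assert np.max(np.abs(c1 - c2)) < 0.01 * np.max(np.abs(c1))

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            KineticParams("tofts", ktrans=-0.1, ve=0.2)
        with pytest.raises(ValueError):
            KineticParams("ex_tofts", ktrans=0.1, ve=0.7, vp=0.4)
        with pytest.raises(ValueError):
            KineticParams("steady_state", v=1.2)


class TestAUC:
    def test_constant_and_ramp(self):
        t = np.linspace(0, 2, 121)
        assert auc_metric(t, np.ones_like(t), (0.5, 1.5)) == pytest.approx(1.0)
        ramp = np.clip(t - 0.5, 0, None)  # 0 -> 1 mM over [0.5, 1.5]
        assert auc_metric(t, ramp, (0.5, 1.5)) == pytest.approx(0.5, abs=1e-9)

    def test_additivity_over_adjacent_windows(self, population_aif):
        t, c = population_aif.times_min, population_aif.conc
        whole = auc_metric(t, c, (1.0, 5.0))
        parts = auc_metric(t, c, (1.0, 2.7)) + auc_metric(t, c, (2.7, 5.0))
        assert whole == pytest.approx(parts, rel=1e-10)

    def test_window_validation(self, population_aif):
        t, c = population_aif.times_min, population_aif.conc
        with pytest.raises(ValueError):
            auc_metric(t, c, (3.0, 3.0))
        with pytest.raises(ValueError):
            auc_metric(t, c, (5.0, 99.0))
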