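"""Two-pass AIF model, fitting, QC criteria and dual-input mixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from dualflow.aif import (
    AIFModelParams,
    ArterialCurve,
    ArterialInputModel,
    DualInputSpec,
    check_dual_aif_criteria,
    evaluate_aif,
    fit_aif,
    net_plasma_input,
)

PARAMS = AIFModelParams(a_b=60.0, mu_b=6.0, a_g=1.0, mu_g=0.2,
                        t_onset=0.1, tau_rc=0.25, kappa_rc=0.3)


def independent_two_pass(p: AIFModelParams, t):
    """Independent term-by-term re-implementation of the model."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for shift, amp in ((p.t_onset, 1.0), (p.t_onset + p.tau_rc, p.kappa_rc)):
        u = t - shift
        live = u >= 0
        term = np.zeros_like(t)
        term[live] = (p.a_b * u[live] * np.exp(-p.mu_b * u[live])
                      + p.a_g * (np.exp(-p.mu_g * u[live]) - np.exp(-p.mu_b * u[live])))
        out += amp * term
    return out


class TestEvaluate:
    def test_zero_before_onset(self):
        t = np.linspace(0.0, 0.0999, 20)
        np.testing.assert_array_equal(evaluate_aif(PARAMS, t), 0.0)

    def test_kappa_zero_degenerates_to_single_pass(self):
        p0 = AIFModelParams(a_b=60.0, mu_b=6.0, a_g=1.0, mu_g=0.2,
                            t_onset=0.1, tau_rc=0.25, kappa_rc=0.0)
        t = np.linspace(0, 5, 301)
        u = np.clip(t - 0.1, 0, None)
        expected = np.where(
            t >= 0.1,
            60.0 * u * np.exp(-6.0 * u) + 1.0 * (np.exp(-0.2 * u) - np.exp(-6.0 * u)),
            0.0,
        )
        np.testing.assert_allclose(evaluate_aif(p0, t), expected, atol=1e-14)

    def test_matches_independent_sum_of_terms(self):
        t = np.linspace(0, 5, 601)
        np.testing.assert_allclose(
            evaluate_aif(PARAMS, t), independent_two_pass(PARAMS, t), atol=1e-12
        )

    def test_finite_integral_matches_quadrature(self):
        # analytic integral of P: a_b/mu_b^2 + a_g (1/mu_g - 1/mu_b), x (1+kappa)
        analytic = (1 + PARAMS.kappa_rc) * (
            PARAMS.a_b / PARAMS.mu_b**2 + PARAMS.a_g * (1 / PARAMS.mu_g - 1 / PARAMS.mu_b)
        )
        num, _ = quad(lambda x: float(evaluate_aif(PARAMS, x)), 0, np.inf, limit=400)
        assert num == pytest.approx(analytic, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AIFModelParams(a_b=60, mu_b=0.1, a_g=1, mu_g=0.2)  # mu_b <= mu_g
        with pytest.raises(ValueError):
            AIFModelParams(a_b=-1, mu_b=6, a_g=1, mu_g=0.2)
        with pytest.raises(ValueError):
            AIFModelParams(a_b=60, mu_b=6, a_g=1, mu_g=0.2, kappa_rc=1.5)


class TestFit:
    def test_noiseless_recovery_within_2pct(self, pa_aif):
        t = np.arange(0, 4.3, 2.0 / 60.0)
        curve = ArterialCurve(times=t, conc_blood=evaluate_aif(pa_aif, t))
        res = fit_aif(curve, seed=3)
        truth = pa_aif.as_dict()
        for k, v in res.params.as_dict().items():
            assert v == pytest.approx(truth[k], rel=0.02, abs=1e-3), k
        assert res.sse < 1e-10 * t.size

    def test_flat_curve_raises(self):
        t = np.arange(0, 4.0, 0.05)
        with pytest.raises(ValueError, match="flat"):
            fit_aif(ArterialCurve(times=t, conc_blood=np.zeros_like(t)))

    def test_too_few_samples_raises(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            ArterialInputModel(ArterialCurve(times=t, conc_blood=np.ones(5)))

    def test_noisy_median_peak_error_below_5pct(self, pa_aif):
        # 100 noisy replicates at SD = 5% of peak; compare fitted peaks
        t = np.arange(0, 4.3, 2.0 / 60.0)
        clean = evaluate_aif(pa_aif, t)
        sd = 0.05 * clean.max()
        rng = np.random.default_rng(11)
        tfine = np.linspace(0, 4.3, 2000)
        true_peak = evaluate_aif(pa_aif, tfine).max()
        errs = []
        for _ in range(100):
            noisy = clean + rng.normal(0, sd, clean.shape)
            res = fit_aif(ArterialCurve(times=t, conc_blood=noisy), n_starts=3, seed=5)
            errs.append(abs(res.predict(tfine).max() - true_peak) / true_peak)
        assert np.median(errs) < 0.05


class TestDualCriteria:
    def _curve(self, aifp, t, site):
        return ArterialCurve(times=t, conc_blood=evaluate_aif(aifp, t), site=site)

    def test_constructed_pair_passes_all(self, pa_aif, ao_aif):
        t = np.arange(0, 4.3, 2.0 / 60.0)
        rep = check_dual_aif_criteria(self._curve(pa_aif, t, "pulmonary"),
                                      self._curve(ao_aif, t, "aortic"))
        assert rep["pa_onset_earlier"]
        assert rep["pa_peak_higher"]
        assert rep["tails_similar"]

    def test_identical_curves_fail_onset(self, pa_aif):
        t = np.arange(0, 4.3, 2.0 / 60.0)
        c = self._curve(pa_aif, t, "pulmonary")
        c2 = ArterialCurve(times=t, conc_blood=c.conc_blood, site="aortic")
        rep = check_dual_aif_criteria(c, c2)
        assert not rep["pa_onset_earlier"]

    def test_higher_aortic_peak_fails_peak_flag(self, pa_aif, ao_aif):
        t = np.arange(0, 4.3, 2.0 / 60.0)
        big_ao = ArterialCurve(times=t, conc_blood=2.0 * evaluate_aif(pa_aif, t),
                              site="aortic")
        rep = check_dual_aif_criteria(self._curve(pa_aif, t, "pulmonary"), big_ao)
        assert not rep["pa_peak_higher"]


class TestNetPlasmaInput:
    def test_single_input_limits(self, pa_aif, ao_aif, dual_spec):
        t = np.linspace(0, 4, 50)
        np.testing.assert_allclose(
            net_plasma_input(dual_spec, 1.0, t), evaluate_aif(pa_aif, t) / 0.55
        )
        np.testing.assert_allclose(
            net_plasma_input(dual_spec, 0.0, t), evaluate_aif(ao_aif, t) / 0.55
        )

    def test_mixing_arithmetic(self, dual_spec, pa_aif, ao_aif):
        # half-and-half mixing of blood values 2 and 1 mM at H_LV = 0.45
        # gives 1.5/0.55 = 2.7272... mM plasma; the same identity must hold
        # pointwise on evaluated curves
        assert (0.5 * 2.0 + 0.5 * 1.0) / 0.55 == pytest.approx(2.727272, rel=1e-5)
        t = np.array([0.5, 1.0, 2.0])
        c_pa = evaluate_aif(pa_aif, t)
        c_a = evaluate_aif(ao_aif, t)
        np.testing.assert_allclose(
            net_plasma_input(dual_spec, 0.5, t),
            (0.5 * c_pa + 0.5 * c_a) / 0.55,
            rtol=1e-12,
        )

    @given(gamma=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_in_gamma(self, gamma, dual_spec):
        t = np.linspace(0, 4, 40)
        c1 = net_plasma_input(dual_spec, 1.0, t)
        c0 = net_plasma_input(dual_spec, 0.0, t)
        mixed = net_plasma_input(dual_spec, gamma, t)
        np.testing.assert_allclose(mixed, gamma * c1 + (1 - gamma) * c0, atol=1e-12)

    def test_mode_forces_gamma(self, pa_aif, ao_aif):
        t = np.linspace(0, 4, 30)
        pulm = DualInputSpec(mode="pulmonary", pulmonary=pa_aif)
        np.testing.assert_allclose(
            net_plasma_input(pulm, 0.3, t), evaluate_aif(pa_aif, t) / 0.55
        )

    def test_gamma_out_of_range_rejected(self, dual_spec):
        with pytest.raises(ValueError):
            net_plasma_input(dual_spec, 1.5, np.array([1.0]))
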