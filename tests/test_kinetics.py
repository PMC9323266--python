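"""Depletion regression, rate laws, ML fitting, BIC selection, bootstraps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pahmix.kinetics import (
    DegenerateDataError,
    DepletionTimeCourse,
    KineticFit,
    KineticModelSpec,
    ModelForm,
    bic,
    bootstrap_rate_ci,
    clint_first_phase,
    fit_exponential_depletion,
    fit_rate_model,
    initial_rate,
    parametric_bootstrap_params,
    rate_model_eval,
    select_model,
)
from pahmix.synth import AssayDesign, generate_depletion_courses, generate_rate_table


def _course(times, concs, s0=0.2, replicate=0, **kw):
    obs = [(float(t), replicate, float(c)) for t, c in zip(times, concs)]
    return DepletionTimeCourse("X", s0, obs, **kw)


class TestExponentialDepletion:
    def test_noiseless_exact_recovery(self):
        t = np.array([0, 5, 10, 20, 30.0])
        c = _course(t, 0.2 * np.exp(-0.05 * t))
        k, s0 = fit_exponential_depletion(c)
        assert abs(k - 0.05) / 0.05 < 1e-8
        assert abs(s0 - 0.2) / 0.2 < 1e-8

    def test_constant_course_flags_no_depletion(self):
        fit = fit_exponential_depletion(_course([0, 5, 10, 20, 30], [0.2] * 5))
        assert fit.no_depletion
        assert fit.k == pytest.approx(0.0, abs=1e-10)
        assert fit.s0 == pytest.approx(0.2, rel=1e-8)

    def test_too_few_timepoints_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_exponential_depletion(_course([0, 10], [0.2, 0.1]))

    def test_all_zero_concentrations_raise(self):
        with pytest.raises(DegenerateDataError):
            fit_exponential_depletion(_course([0, 5, 10], [0, 0, 0]))

    def test_noisy_estimates_unbiased_in_first_order_regime(self):
        """Monte-Carlo oracle: over many seeds the mean fitted k approaches the
        generating k (CLT band computed from the same draws)."""
        spec = KineticModelSpec(ModelForm.MM, vmax1=1.0, km1=100.0)
        k_true = rate_model_eval(spec, 0.2) / 0.2 * 2.0  # first-order: v/S × protein
        design = AssayDesign(
            substrate_id="X", s0_list=(0.2,), time_points=(0, 10, 20, 40, 60), noise_cv=0.05
        )
        ks = []
        for seed in range(100):
            (course,) = generate_depletion_courses(design, spec, seed=seed)
            ks.append(fit_exponential_depletion(course).k)
        ks = np.asarray(ks)
        band = 3 * ks.std(ddof=1) / math.sqrt(ks.size)
        assert abs(ks.mean() - k_true) < band


class TestInitialRate:
    @pytest.mark.parametrize(
        "k,s0,vol,prot,expected",
        [(0.05, 0.2, 0.5, 2.0, 0.005), (0.0, 1.0, 0.5, 2.0, 0.0), (0.1, 1.0, 0.5, 2.0, 0.05)],
    )
    def test_unit_conversion(self, k, s0, vol, prot, expected):
        assert initial_rate(k, s0, vol, prot) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("vol,prot", [(0.0, 2.0), (0.5, 0.0), (-1.0, 2.0)])
    def test_nonpositive_geometry_raises(self, vol, prot):
        with pytest.raises(ValueError):
            initial_rate(0.05, 0.2, vol, prot)


class TestRateModelEval:
    def test_zero_at_zero_substrate(self, bap_spec):
        assert rate_model_eval(bap_spec, 0.0) == 0.0

    def test_mm_clearance_hand_value(self, bap_spec):
        # 0.0063·0.14/(0.088+0.14) + 0.0012·0.14, worked by hand
        assert rate_model_eval(bap_spec, 0.14) == pytest.approx(0.0040364, rel=1e-4)

    def test_negative_substrate_raises(self, bap_spec):
        with pytest.raises(ValueError):
            rate_model_eval(bap_spec, -0.1)

    def test_nested_model_identities(self):
        S = np.linspace(0, 5, 40)
        mm = KineticModelSpec(ModelForm.MM, vmax1=0.01, km1=0.2)
        mmc = KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=0.01, km1=0.2, clint2=1e-30)
        dmm = KineticModelSpec(ModelForm.DOUBLE_MM, vmax1=0.01, km1=0.2, vmax2=1e-30, km2=1.0)
        np.testing.assert_allclose(rate_model_eval(mmc, S), rate_model_eval(mm, S), atol=1e-12)
        np.testing.assert_allclose(rate_model_eval(dmm, S), rate_model_eval(mm, S), atol=1e-12)

    @given(
        vmax=st.floats(1e-4, 1.0),
        km=st.floats(1e-3, 10.0),
        clint=st.floats(1e-6, 0.1),
        s1=st.floats(1e-6, 10.0),
        s2=st.floats(1e-6, 10.0),
    )
    def test_strictly_increasing_in_substrate(self, vmax, km, clint, s1, s2):
        spec = KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=vmax, km1=km, clint2=clint)
        lo, hi = sorted((s1, s2))
        if hi > lo:
            assert rate_model_eval(spec, hi) > rate_model_eval(spec, lo)

    def test_double_mm_requires_km_ordering(self):
        with pytest.raises(ValueError):
            KineticModelSpec(ModelForm.DOUBLE_MM, vmax1=0.01, km1=1.0, vmax2=0.01, km2=0.5)


_RECOVERY_SPECS = [
    KineticModelSpec(ModelForm.MM, vmax1=0.005, km1=0.1),
    KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=0.00090, km1=0.060, clint2=0.0017),
    KineticModelSpec(ModelForm.DOUBLE_MM, vmax1=0.005, km1=0.05, vmax2=0.02, km2=5.0),
]


class TestFitRateModel:
    @pytest.mark.parametrize("spec", _RECOVERY_SPECS, ids=lambda s: s.form.value)
    def test_noiseless_parameter_recovery(self, spec):
        S = np.geomspace(0.025, 1.0, 12)
        fit = fit_rate_model((S, rate_model_eval(spec, S)), spec.form)
        for name in spec.param_names():
            true = getattr(spec, name)
            assert abs(getattr(fit.spec, name) - true) / true < 1e-4

    def test_all_zero_rates_flagged_degenerate(self):
        S = np.geomspace(0.05, 2.5, 8)
        fit = fit_rate_model((S, np.zeros_like(S)), ModelForm.MM)
        assert fit.degenerate

    def test_insufficient_distinct_concentrations(self):
        with pytest.raises(DegenerateDataError):
            fit_rate_model((np.array([0.1, 0.1, 0.2]), np.array([1.0, 1.0, 2.0])), ModelForm.MM_CLEARANCE)

    def test_nesting_mm_within_mm_clearance(self):
        mm = KineticModelSpec(ModelForm.MM, vmax1=0.0063, km1=0.088)
        S = np.geomspace(0.05, 2.5, 12)
        # noiseless: exact recovery, clint2 pinned toward the lower bound
        fit_exact = fit_rate_model((S, rate_model_eval(mm, S)), ModelForm.MM)
        assert abs(fit_exact.spec.vmax1 - 0.0063) / 0.0063 < 1e-4
        fit_mmc0 = fit_rate_model((S, rate_model_eval(mm, S)), ModelForm.MM_CLEARANCE)
        assert fit_mmc0.spec.clint2 < 1e-6
        # noisy: the nested model can never fit better than its extension
        design = AssayDesign(substrate_id="X", s0_list=tuple(S), replicates=3)
        rates = generate_rate_table(design, mm, noise_cv=0.05, seed=17)
        fit_mm = fit_rate_model(rates, ModelForm.MM)
        fit_mmc = fit_rate_model(rates, ModelForm.MM_CLEARANCE)
        # equality only up to optimiser tolerance when clint2 sits on its bound
        assert fit_mmc.rss <= fit_mm.rss * (1 + 1e-6)
        assert fit_mmc.loglik >= fit_mm.loglik - 1e-4

    def test_ml_argmin_equals_least_squares(self, bap_spec):
        """Profiling sigma out of the Gaussian likelihood must leave the same
        kinetic-parameter argmin as plain RSS minimisation (independent
        joint-likelihood optimisation as oracle)."""
        from scipy.optimize import minimize

        design = AssayDesign(substrate_id="BaP", s0_list=tuple(np.geomspace(0.05, 2.5, 12)))
        rates = generate_rate_table(design, bap_spec, noise_cv=0.05, seed=7)
        S = np.array([r.S for r in rates])
        y = np.array([r.rate for r in rates])
        fit = fit_rate_model(rates, ModelForm.MM_CLEARANCE)
        p_ls = fit.spec.param_vector()
        n = y.size

        def nll(x):
            v = np.exp(x[0]) * S / (np.exp(x[1]) + S) + np.exp(x[2]) * S
            s2 = np.exp(2 * x[3])
            return 0.5 * (n * np.log(2 * np.pi * s2) + np.sum((v - y) ** 2) / s2)

        x0 = np.concatenate([np.log(p_ls * 1.3), [np.log(fit.sigma_hat * 0.7)]])
        sol = minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-14, "fatol": 1e-14, "maxiter": 100000, "maxfev": 100000},
        )
        p_ml = np.exp(sol.x[:3])
        assert np.max(np.abs(p_ml - p_ls) / p_ls) < 1e-8


class TestBicSelection:
    def _fit(self, form, loglik, n=10):
        specs = {
            ModelForm.MM: KineticModelSpec(ModelForm.MM, vmax1=1.0, km1=1.0),
            ModelForm.MM_CLEARANCE: KineticModelSpec(ModelForm.MM_CLEARANCE, vmax1=1.0, km1=1.0, clint2=1.0),
        }
        f = KineticFit(spec=specs[form], sigma_hat=1.0, loglik=loglik, bic=0.0, n_obs=n, rss=1.0)
        f.bic = bic(f)
        return f

    def test_bic_penalises_extra_parameter_by_log_n(self):
        f_mm = self._fit(ModelForm.MM, loglik=-5.0)
        f_mmc = self._fit(ModelForm.MM_CLEARANCE, loglik=-5.0)
        assert f_mmc.bic - f_mm.bic == pytest.approx(math.log(10), rel=1e-12)

    def test_bic_decreases_with_loglik(self):
        assert self._fit(ModelForm.MM, -4.0).bic < self._fit(ModelForm.MM, -5.0).bic

    def test_select_single_fit_returns_itself(self):
        f = self._fit(ModelForm.MM, -5.0)
        assert select_model([f]) is f

    def test_select_argmin_of_three(self, bap_spec):
        S = np.geomspace(0.05, 2.5, 12)
        y = rate_model_eval(bap_spec, S)
        fits = [fit_rate_model((S, y), form) for form in ModelForm]
        best = select_model(fits)
        assert best.bic == min(f.bic for f in fits)
        assert best.spec.form is ModelForm.MM_CLEARANCE

    def test_tie_prefers_fewer_parameters(self):
        f_mm = self._fit(ModelForm.MM, loglik=-5.0)
        f_mmc = self._fit(ModelForm.MM_CLEARANCE, loglik=-5.0)
        f_mmc.bic = f_mm.bic  # force an exact tie
        assert select_model([f_mmc, f_mm]).spec.form is ModelForm.MM

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            select_model([])


class TestBootstrapRateCI:
    def _noisy_course(self, seed):
        design = AssayDesign(
            substrate_id="X", s0_list=(0.2,), time_points=(0, 5, 10, 20, 30), noise_cv=0.10
        )
        spec = KineticModelSpec(ModelForm.MM, vmax1=1.0, km1=100.0)
        return generate_depletion_courses(design, spec, seed=seed)[0]

    def test_noiseless_course_collapses_ci(self):
        t = np.array([0, 5, 10, 20, 30.0])
        obs = []
        for rep in range(3):
            obs += [(float(tt), rep, float(0.2 * math.exp(-0.05 * tt))) for tt in t]
        course = DepletionTimeCourse("X", 0.2, obs)
        r = bootstrap_rate_ci(course, n_boot=100, seed=0)
        assert r.ci_low == pytest.approx(r.rate, rel=1e-9)
        assert r.ci_high == pytest.approx(r.rate, rel=1e-9)

    def test_seed_determinism(self):
        course = self._noisy_course(1)
        a = bootstrap_rate_ci(course, n_boot=200, seed=99)
        b = bootstrap_rate_ci(course, n_boot=200, seed=99)
        assert (a.ci_low, a.ci_high, a.rate) == (b.ci_low, b.ci_high, b.rate)

    def test_ci_brackets_point_estimate(self):
        r = bootstrap_rate_ci(self._noisy_course(2), n_boot=200, seed=3)
        assert r.ci_low <= r.rate <= r.ci_high

    def test_too_few_bootstrap_samples(self):
        with pytest.raises(ValueError):
            bootstrap_rate_ci(self._noisy_course(3), n_boot=1)


class TestParametricBootstrap:
    def test_zero_sigma_collapses_cis(self, dbc_spec):
        S = np.geomspace(0.025, 1.0, 12)
        rates = (S, rate_model_eval(dbc_spec, S))
        fit = fit_rate_model(rates, ModelForm.MM_CLEARANCE)
        cis = parametric_bootstrap_params(fit, rates, n_boot=50, seed=0)
        for name, (lo, hi) in cis.items():
            point = getattr(fit.spec, name)
            assert lo == pytest.approx(point, rel=1e-6)
            assert hi == pytest.approx(point, rel=1e-6)

    def test_seed_reproducibility_and_bracketing(self, bap_spec):
        design = AssayDesign(substrate_id="BaP", s0_list=tuple(np.geomspace(0.05, 2.5, 12)))
        rates = generate_rate_table(design, bap_spec, noise_cv=0.05, seed=11)
        fit = fit_rate_model(rates, ModelForm.MM_CLEARANCE)
        a = parametric_bootstrap_params(fit, rates, n_boot=100, seed=5)
        b = parametric_bootstrap_params(fit, rates, n_boot=100, seed=5)
        assert a == b
        for name, (lo, hi) in a.items():
            assert lo <= getattr(fit.spec, name) <= hi

    def test_rejects_tiny_n_boot(self, bap_spec):
        S = np.geomspace(0.05, 2.5, 12)
        rates = (S, rate_model_eval(bap_spec, S))
        fit = fit_rate_model(rates, ModelForm.MM_CLEARANCE)
        with pytest.raises(ValueError):
            parametric_bootstrap_params(fit, rates, n_boot=1)


class TestClint:
    def test_identity(self):
        assert clint_first_phase(0.42, 1.0) == 0.42

    def test_zero_km_raises(self):
        with pytest.raises(ValueError):
            clint_first_phase(0.1, 0.0)

    def test_fit_exposes_clint1(self, bap_spec):
        S = np.geomspace(0.05, 2.5, 12)
        fit = fit_rate_model((S, rate_model_eval(bap_spec, S)), ModelForm.MM_CLEARANCE)
        assert fit.clint1 == pytest.approx(fit.spec.vmax1 / fit.spec.km1, rel=1e-12)
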