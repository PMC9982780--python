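"""MAP objective, individual and population fitting, LRT, bootstrap, GOF."""

import numpy as np
import pytest

import floxpk as fx
from floxpk.estimation import (
    _free_eta_names,
    _map_gradient,
    fit_individual,
    map_objective,
)


def _make_patient(params, regimen, times, model, pid="T1", covariates=None, rng=None):
    """Patient with dual-channel observations on the given model curve,
    optionally with proportional noise."""
    cov = covariates or fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
    doses = regimen.dose_events(max(times) + 1.0)
    obs = []
    for t in sorted(times):
        c = fx.concentration_total(params, doses, float(t))
        for ch, true in (("total", c), ("unbound", params.f_u * c)):
            val = true
            if rng is not None:
                val = true * (1.0 + model.sigma(ch) * rng.standard_normal())
                while val <= 0:
                    val = true * (1.0 + model.sigma(ch) * rng.standard_normal())
            obs.append(fx.Observation(float(t), ch, float(val)))
    return fx.PatientRecord(pid, doses, obs, cov)


@pytest.fixture(scope="module")
def rich_patient(final_model, q4h_regimen):
    """Noise-free rich profile generated at known etas (identifiable set:
    no IIV on the albumin exponent)."""
    m = final_model.replace(iiv={"fr": 71.0, "v": 84.0, "fu": 26.0, "ex": 0.0})
    etas = {"fr": 0.35, "v": -0.25, "fu": 0.15}
    cov = fx.CovariateSet(weight=70.0, albumin=25.0, clcr=80.0)
    params = fx.individual_parameters(m, cov, etas)
    times = np.concatenate([np.linspace(1.0, 3.9, 12), np.linspace(40.0, 43.9, 12)])
    return m, etas, _make_patient(params, fx.DosingRegimen(12000.0, "intermittent", interval=4.0, infusion_duration=0.5), times, m, covariates=cov)


class TestMapObjective:
    def test_zero_residuals_leave_only_log_variance_terms(self, final_model, q4h_regimen):
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        params = fx.individual_parameters(final_model, cov)
        pat = _make_patient(params, q4h_regimen, [25.0, 26.5, 27.5], final_model, covariates=cov)
        x = np.zeros(len(_free_eta_names(final_model)))
        got = map_objective(x, pat, final_model)
        expected = 0.0
        doses = q4h_regimen.dose_events(30.0)
        for o in pat.observations:
            c = fx.concentration_total(params, doses, o.time)
            pred = c if o.channel == "total" else params.f_u * c
            expected += np.log((final_model.sigma(o.channel) * pred) ** 2)
        for name in _free_eta_names(final_model):
            expected += np.log(final_model.omega(name) ** 2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_duplicate_perfect_observation_adds_only_its_constant(self, final_model, q4h_regimen):
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        params = fx.individual_parameters(final_model, cov)
        pat1 = _make_patient(params, q4h_regimen, [25.0, 26.0], final_model, covariates=cov)
        pat2 = fx.PatientRecord("T2", pat1.dose_events, pat1.observations + [pat1.observations[-1]], cov)
        x = np.zeros(len(_free_eta_names(final_model)))
        o = pat1.observations[-1]
        const = np.log((final_model.sigma(o.channel) * o.value) ** 2)
        assert map_objective(x, pat2, final_model) == pytest.approx(
            map_objective(x, pat1, final_model) + const, rel=1e-12
        )

    def test_invariant_to_observation_order(self, final_model, q4h_regimen):
        rng = np.random.default_rng(3)
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        params = fx.individual_parameters(final_model, cov)
        pat = _make_patient(params, q4h_regimen, [25.0, 26.0, 27.0], final_model, covariates=cov, rng=rng)
        x = rng.normal(0, 0.3, len(_free_eta_names(final_model)))
        # legal reordering: swap the two channels at each tied time point
        reordered = []
        for i in range(0, len(pat.observations), 2):
            reordered.extend(pat.observations[i:i + 2][::-1])
        shuffled = fx.PatientRecord("S", pat.dose_events, reordered, cov)
        assert map_objective(x, shuffled, final_model) == pytest.approx(
            map_objective(x, pat, final_model), rel=1e-12
        )

    def test_observation_before_dosing_is_an_error(self, final_model):
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        pat = fx.PatientRecord(
            "Z",
            [fx.DoseEvent(1.0, 2000.0, 0.5)],
            [fx.Observation(0.5, "total", 3.0)],
            cov,
        )
        with pytest.raises(ValueError, match="precedes any"):
            map_objective(np.zeros(len(_free_eta_names(final_model))), pat, final_model)

    def test_complex_step_gradient_matches_central_differences(self, rich_patient):
        m, _, pat = rich_patient
        x = np.array([0.1, -0.3, 0.2])
        g = _map_gradient(x, pat, m)
        num = np.empty_like(g)
        for j in range(len(x)):
            e = np.zeros(len(x))
            e[j] = 1e-6
            num[j] = (map_objective(x + e, pat, m) - map_objective(x - e, pat, m)) / 2e-6
        assert np.allclose(g, num, rtol=1e-4)


class TestFitIndividual:
    def test_no_observations_returns_prior_mode(self, final_model):
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        pat = fx.PatientRecord("E", [fx.DoseEvent(0.0, 2000.0, 0.5)], [], cov)
        est = fit_individual(pat, final_model)
        assert all(v == 0.0 for v in est.etas.values())
        assert est.params.cl_total == pytest.approx(75.24)

    def test_recovers_etas_from_rich_noise_free_profile(self, rich_patient):
        m, true_etas, pat = rich_patient
        est = fit_individual(pat, m.replace(sigma_total=1.0, sigma_unbound=1.0))
        for name, val in true_etas.items():
            assert est.etas[name] == pytest.approx(val, abs=1e-2)

    def test_prior_washout_approaches_unpenalized_fit(self, rich_patient):
        """With enormous omegas the MAP fit reproduces the unpenalized
        (pure likelihood) solution, which for noise-free data is the
        generating parameter set."""
        m, true_etas, pat = rich_patient
        # small sigma keeps the extended-least-squares ln-variance term from
        # pulling the optimum off the zero-residual solution
        washed = m.replace(
            iiv={"fr": 1e6, "v": 1e6, "fu": 1e6, "ex": 0.0}, sigma_total=1.0, sigma_unbound=1.0
        )
        est = fit_individual(pat, washed)
        cov = pat.covariates
        truth = fx.individual_parameters(m, cov, true_etas)
        assert est.params.cl_total == pytest.approx(truth.cl_total, rel=0.01)
        assert est.params.v == pytest.approx(truth.v, rel=0.01)
        assert est.params.f_u == pytest.approx(truth.f_u, rel=0.01)


class TestFitPopulation:
    def test_degenerate_data_rejected(self, final_model):
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        p1 = fx.PatientRecord("A", [fx.DoseEvent(0.0, 2000.0, 0.5)], [fx.Observation(1.0, "total", 5.0)], cov)
        with pytest.raises(ValueError):
            fx.fit_population([p1])
        p2 = fx.PatientRecord("B", [fx.DoseEvent(0.0, 2000.0, 0.5)], [], cov)
        with pytest.raises(ValueError):
            fx.fit_population([p1, p2])

    def test_patient_order_irrelevant(self, small_study):
        a = fx.fit_population(small_study.patients, max_iter=3)
        b = fx.fit_population(small_study.patients[::-1], max_iter=3)
        assert a.model.f_r == pytest.approx(b.model.f_r, rel=1e-9)
        assert a.model.sigma_total == pytest.approx(b.model.sigma_total, rel=1e-9)
        assert a.ofv == pytest.approx(b.ofv, rel=1e-9)

    def test_ofv_decreases_in_pure_map_mode(self, small_study):
        fit = fx.fit_population(
            small_study.patients,
            max_iter=25,
            estep_samples=0,
            variance_correction=False,
        )
        diffs = np.diff(fit.ofv_history)
        assert np.all(diffs <= 1e-6 * np.maximum(np.abs(fit.ofv_history[:-1]), 1.0))

    def test_truth_init_does_not_increase_ofv_first_iteration(self, small_study):
        fit = fx.fit_population(
            small_study.patients,
            init=small_study.truth,
            max_iter=2,
            estep_samples=0,
            variance_correction=False,
        )
        assert fit.ofv_history[-1] <= fit.ofv_history[0] + 1e-6 * abs(fit.ofv_history[0])


class TestLikelihoodRatioTest:
    def test_printed_model_comparisons(self):
        # dOFV 961-957 = 887-883 = 4 on 1 df
        assert fx.likelihood_ratio_test(961.0, 957.0, 1) == pytest.approx(0.0455, abs=5e-5)
        assert fx.likelihood_ratio_test(887.0, 883.0, 1) == pytest.approx(0.0455, abs=5e-5)
        # dOFV 961-887 = 74 on 1 df
        assert fx.likelihood_ratio_test(961.0, 887.0, 1) < 1e-4

    def test_no_improvement_and_negative_delta(self):
        assert fx.likelihood_ratio_test(100.0, 100.0, 1) == 1.0
        assert fx.likelihood_ratio_test(100.0, 105.0, 1) == 1.0

    def test_monotone_decreasing_in_delta(self):
        ps = [fx.likelihood_ratio_test(100.0 + d, 100.0, 1) for d in (0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0.0 < p <= 1.0 for p in ps)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            fx.likelihood_ratio_test(10.0, 5.0, 0)


class TestGofBiasPrecision:
    def test_perfect_prediction(self):
        assert fx.gof_bias_precision([10.0, 5.0], [10.0, 5.0]) == (0.0, 0.0)

    def test_single_pair(self):
        bias, precision = fx.gof_bias_precision([10.0], [8.0])
        assert bias == pytest.approx(-20.0)
        assert precision == pytest.approx(20.0)

    def test_bias_cancels_but_rmse_does_not(self):
        bias, precision = fx.gof_bias_precision([10.0, 10.0], [8.0, 12.0])
        assert bias == pytest.approx(0.0)
        assert precision == pytest.approx(20.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fx.gof_bias_precision([], [])
        with pytest.raises(ValueError):
            fx.gof_bias_precision([0.0], [1.0])


class TestBootstrap:
    def test_identical_patients_give_zero_width_ci(self, final_model, q4h_regimen):
        rng = np.random.default_rng(17)
        cov = fx.CovariateSet(weight=70.0, albumin=21.2, clcr=66.0)
        params = fx.individual_parameters(final_model, cov)
        base = _make_patient(params, q4h_regimen, np.linspace(24.0, 27.5, 8), final_model,
                             covariates=cov, rng=rng)
        clones = [
            fx.PatientRecord(f"C{i}", base.dose_events, base.observations, cov) for i in range(6)
        ]
        # the variance components collapse toward the boundary here (the
        # log-likelihood is unbounded in ln omega^2 for identical patients),
        # so a coarse OFV tolerance is the appropriate stopping rule
        summary = fx.bootstrap_population(
            clones, n_boot=4, seed=5, max_iter=80, n_starts=1, estep_samples=0, ofv_rtol=1e-2
        )
        assert summary.n_failed == 0
        width = summary.ci_high - summary.ci_low
        assert float(width.abs().max()) == pytest.approx(0.0, abs=1e-9)

    def test_fixed_seed_reproducible(self, small_study):
        kw = dict(n_boot=3, seed=11, max_iter=4, n_starts=1)
        a = fx.bootstrap_population(small_study.patients, **kw)
        b = fx.bootstrap_population(small_study.patients, **kw)
        assert a.replicates.equals(b.replicates)

    def test_invalid_n_boot(self, small_study):
        with pytest.raises(ValueError):
            fx.bootstrap_population(small_study.patients, n_boot=0, seed=1)
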