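"""MAP Bayesian individual fitting and iterative two-stage (ITS) population
estimation.

Each patient's random effects (etas) are estimated by minimizing a
-2 log-posterior combining proportional-error data likelihood per channel
(total / unbound) with the lognormal population prior.  The population step
alternates MAP fits (E-step) with closed-form updates of the typical
values, IIV variances and residual variances (M-step); the variance updates
include the Laplace-approximate posterior uncertainty of the etas, the
EM-type correction that counteracts MAP shrinkage.  The objective function
value (OFV) is the sum of individual -2 log-posterior contributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariates import (
    CovariateSet,
    PopulationModel,
    _raw_individual_parameters,
    cv_to_omega,
    omega_to_cv,
)
from .pk import (
    DoseEvent,
    IndividualParameters,
    _conc_from_design,
    _conc_total_raw,
    _superposition_design,
)

__all__ = [
    "Observation",
    "PatientRecord",
    "IndividualEstimate",
    "PopulationModelFit",
    "map_objective",
    "fit_individual",
    "fit_population",
    "likelihood_ratio_test",
    "bootstrap_population",
    "BootstrapSummary",
    "gof_bias_precision",
    "population_predictions",
]

CHANNELS = ("total", "unbound")


@dataclass(frozen=True)
class Observation:
    """A measured serum concentration: ``channel`` is 'total' or 'unbound'."""

    time: float
    channel: str
    value: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not self.value > 0:
            raise ValueError(f"observed concentration must be positive, got {self.value}")
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")


@dataclass
class PatientRecord:
    """One subject: dosing history, timed observations, covariates."""

    id: str
    dose_events: list
    observations: list
    covariates: CovariateSet

    def __post_init__(self) -> None:
        if len(self.dose_events) == 0:
            raise ValueError(f"patient {self.id}: at least one dose event is required")
        times = [o.time for o in self.observations]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"patient {self.id}: observations must be time-ordered")


@dataclass
class IndividualEstimate:
    """MAP estimate for one patient."""

    params: IndividualParameters
    etas: dict
    ofv_contribution: float
    converged: bool = True
    posterior_cov: Optional[np.ndarray] = None
    pred: Optional[np.ndarray] = None       # MAP predictions per observation
    pred_grad: Optional[np.ndarray] = None  # d pred / d eta at the MAP
    post_mean: Optional[np.ndarray] = None  # importance-sampled posterior mean
    post_var: Optional[np.ndarray] = None   # posterior variance (diagonal)
    rel2: Optional[np.ndarray] = None       # posterior E[(y-pred)^2/pred^2] per obs


@dataclass
class PopulationModelFit:
    """Result of :func:`fit_population`."""

    model: PopulationModel
    ofv: float
    individuals: list
    converged: bool
    n_iterations: int
    ofv_history: list = field(default_factory=list)


def _free_eta_names(m: PopulationModel) -> tuple[str, ...]:
    return tuple(n for n in m.eta_names if m.iiv.get(n, 0.0) > 0)


def _obs_arrays(patient: PatientRecord):
    times = np.array([o.time for o in patient.observations], dtype=float)
    values = np.array([o.value for o in patient.observations], dtype=float)
    is_total = np.array([o.channel == "total" for o in patient.observations], dtype=bool)
    return times, values, is_total


def _patient_data(patient: PatientRecord):
    """Observation arrays plus the parameter-independent superposition
    design, cached on the record (observation/dose lists are treated as
    immutable once fitting starts)."""
    cache = getattr(patient, "_floxpk_cache", None)
    if cache is None:
        times, values, is_total = _obs_arrays(patient)
        design = _superposition_design(patient.dose_events, times)
        cache = (times, values, is_total, design)
        patient._floxpk_cache = cache
    return cache


def _predict(cl, v, fu, patient: PatientRecord, times=None, is_total=None):
    """Model predictions per observation (complex-safe in cl, v, fu)."""
    _, _, cached_is_total, design = _patient_data(patient)
    if is_total is None:
        is_total = cached_is_total
    total = _conc_from_design(cl, v, *design)
    return np.where(is_total, total, fu * total)


def map_objective(
    etas: Sequence[float], patient: PatientRecord, m: PopulationModel
) -> float:
    """-2 log-posterior of one patient's random effects.

    Data term per observation: ``((y - pred) / (sigma_ch * pred))^2 +
    ln((sigma_ch * pred)^2)`` with channel-specific proportional error;
    prior term per free eta: ``eta^2 / omega^2 + ln(omega^2)``.  ``etas``
    is ordered by the model variant's free random-effect names.
    """
    return _map_objective_impl(np.asarray(etas), patient, m)


def _map_objective_impl(x, patient: PatientRecord, m: PopulationModel):
    names = _free_eta_names(m)
    if len(x) != len(names):
        raise ValueError(f"expected {len(names)} etas {names}, got {len(x)}")
    cl, v, fu = _raw_individual_parameters(m, patient.covariates, dict(zip(names, x)))
    obj = x.dtype.type(0) if np.iscomplexobj(x) else 0.0
    if patient.observations:
        times, values, is_total, _ = _patient_data(patient)
        first_dose = min(d.start_time for d in patient.dose_events)
        if np.any(times <= first_dose):
            bad = times[times <= first_dose]
            raise ValueError(
                f"patient {patient.id}: observation at t={bad[0]:g} h precedes any "
                "drug delivery; the prediction is zero and proportional error is undefined"
            )
        pred = _predict(cl, v, fu, patient, times, is_total)
        # guard against exponential underflow at extreme trial parameters;
        # the huge resulting residual steers the optimizer back
        pred = np.where(np.real(pred) < 1e-12, 1e-12, pred)
        sig = np.where(is_total, m.sigma("total"), m.sigma("unbound"))
        sd = sig * pred
        obj = obj + np.sum(((values - pred) / sd) ** 2 + np.log(sd**2))
    for name, eta in zip(names, x):
        w2 = m.omega(name) ** 2
        obj = obj + eta**2 / w2 + np.log(w2)
    return obj if np.iscomplexobj(x) else float(obj)


_CS_H = 1e-20


def _map_gradient(x, patient, m):
    """Exact gradient via complex-step differentiation."""
    g = np.empty(len(x))
    for j in range(len(x)):
        xc = x.astype(complex)
        xc[j] += 1j * _CS_H
        g[j] = np.imag(_map_objective_impl(xc, patient, m)) / _CS_H
    return g


def _prediction_gradients(x, patient, m):
    """d pred / d eta (n_obs x n_eta), complex-step, at etas ``x``."""
    names = _free_eta_names(m)
    times, _, is_total, _ = _patient_data(patient)
    G = np.empty((len(times), len(x)))
    for j in range(len(x)):
        xc = x.astype(complex)
        xc[j] += 1j * _CS_H
        cl, v, fu = _raw_individual_parameters(m, patient.covariates, dict(zip(names, xc)))
        G[:, j] = np.imag(_predict(cl, v, fu, patient, is_total=is_total)) / _CS_H
    return G


def _objective_batch(X, patient, m):
    """-2 log-posterior and relative squared residuals for a batch of eta
    vectors (rows of ``X``), fully vectorized."""
    names = _free_eta_names(m)
    e = {name: X[:, j] for j, name in enumerate(names)}
    cl, v, fu = _raw_individual_parameters(m, patient.covariates, e)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    fu = np.asarray(fu, dtype=float)
    _, values, is_total, (rates, a, b) = _patient_data(patient)
    k = (cl / v)[:, None, None]
    total = np.sum(rates * (np.exp(-k * b) - np.exp(-k * (a + b))), axis=1) / cl[:, None]
    pred = np.where(is_total, total, fu[:, None] * total)
    pred = np.maximum(pred, 1e-12)
    sig = np.where(is_total, m.sigma("total"), m.sigma("unbound"))
    sd = sig * pred
    rel2 = ((values - pred) / pred) ** 2
    obj = np.sum(((values - pred) / sd) ** 2 + np.log(sd**2), axis=1)
    for j, name in enumerate(names):
        w2 = m.omega(name) ** 2
        obj = obj + X[:, j] ** 2 / w2 + np.log(w2)
    return obj, rel2


def _importance_refine(patient, m, x_map, cov, Z):
    """Importance-sampled posterior mean/variance of the etas and posterior
    expectation of relative squared residuals, using an antithetic Gaussian
    proposal centered at the MAP with inflated Laplace covariance."""
    n = len(x_map)
    L = np.linalg.cholesky(cov * 1.5 + 1e-10 * np.eye(n))
    Zf = np.vstack([Z, -Z])
    X = x_map + Zf @ L.T
    obj, rel2 = _objective_batch(X, patient, m)
    logq = -0.5 * np.sum(Zf**2, axis=1)  # proposal log-density up to constants
    logw = -0.5 * obj - logq
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    post_mean = w @ X
    centered = X - post_mean
    post_var = w @ centered**2
    rel2_post = w @ rel2
    return post_mean, post_var, rel2_post


def _posterior_covariance(x, patient, m, pred=None, G=None):
    """Gauss-Newton Laplace posterior covariance of the etas,
    ``inv(G' W G + diag(1/omega^2))`` with W the inverse proportional-error
    variances at the MAP predictions."""
    names = _free_eta_names(m)
    if G is None:
        G = _prediction_gradients(x, patient, m)
    if pred is None:
        cl, v, fu = _raw_individual_parameters(m, patient.covariates, dict(zip(names, x)))
        pred = np.real(_predict(cl, v, fu, patient))
    _, _, is_total, _ = _patient_data(patient)
    sig = np.where(is_total, m.sigma("total"), m.sigma("unbound"))
    w = 1.0 / np.maximum(sig * pred, 1e-12) ** 2
    H = G.T @ (G * w[:, None]) + np.diag([1.0 / m.omega(n) ** 2 for n in names])
    vals, vecs = np.linalg.eigh((H + H.T) / 2.0)
    vals = np.maximum(vals, 1e-10)
    return (vecs / vals) @ vecs.T


def fit_individual(
    patient: PatientRecord,
    m: PopulationModel,
    n_starts: int = 5,
    x0: Optional[np.ndarray] = None,
    with_posterior: bool = False,
) -> IndividualEstimate:
    """MAP estimate of one patient's etas by multi-start L-BFGS-B.

    With no observations (or no free random effects) the prior mode
    ``etas = 0`` is returned.  Non-convergence of every start is flagged
    via ``converged=False``, never silently.
    """
    names = _free_eta_names(m)
    if not names or not patient.observations:
        x = np.zeros(len(names))
        est_etas = dict(zip(names, x))
        params = _params_at(m, patient, est_etas)
        ofv = map_objective(x, patient, m) if len(names) else 0.0
        return IndividualEstimate(params, est_etas, ofv, True)

    rng = np.random.default_rng(zlib.crc32(str(patient.id).encode()) % 2**31)
    starts = [np.zeros(len(names)) if x0 is None else np.asarray(x0, dtype=float)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(starts[0] + rng.normal(0.0, 0.5, len(names)))

    best = None
    any_ok = False
    for s in starts:
        res = optimize.minimize(
            _map_objective_impl,
            s,
            args=(patient, m),
            jac=_map_gradient,
            method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * len(names),  # >10 SD; blocks overflow excursions
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        fun = res.fun if np.isfinite(res.fun) else np.inf
        any_ok = any_ok or (bool(res.success) and np.isfinite(res.fun))
        if best is None or fun < best[0]:
            best = (fun, res)
    best_fun, best_res = best
    x = best_res.x
    etas = dict(zip(names, x))
    pred = grad = cov = None
    if with_posterior:
        cl, v, fu = _raw_individual_parameters(m, patient.covariates, etas)
        pred = np.real(_predict(cl, v, fu, patient))
        grad = _prediction_gradients(x, patient, m)
        cov = _posterior_covariance(x, patient, m, pred=pred, G=grad)
    return IndividualEstimate(
        _params_at(m, patient, etas), etas, float(best_fun), any_ok, cov, pred, grad
    )


def _params_at(m, patient, etas) -> IndividualParameters:
    from .covariates import individual_parameters

    return individual_parameters(m, patient.covariates, etas)


_ETA_FIELD = {"fr": "f_r", "cl": "cl_typ_base", "v": "v_typ", "fu": "f_u_pop", "ex": "ex"}


def fit_population(
    data: Sequence[PatientRecord],
    variant: str = "final",
    init: Optional[PopulationModel] = None,
    *,
    max_iter: int = 100,
    ofv_rtol: float = 1e-4,
    n_starts: int = 5,
    variance_correction: bool = True,
    estep_samples: int = 300,
    seed: int = 0,
    min_sigma: float = 0.5,
) -> PopulationModelFit:
    """Iterative two-stage population fit.

    E-step: MAP-fit every patient under the current population model; with
    ``estep_samples > 0`` the MAP mode is refined to the posterior mean by
    antithetic importance sampling around the Laplace approximation (common
    random numbers across iterations, seeded by ``seed``), which removes
    the asymmetry bias the skewed lognormal random effects otherwise leave
    in the mode.  M-step: multiply each typical value by ``exp(mean eta)``
    (the exact EM update for lognormal individual parameters), set
    ``omega^2`` to the empirical variance of the posterior means plus the
    mean posterior variance, and set each channel's proportional error to
    the RMS of posterior-expected relative residuals.  Iterates until the
    relative OFV change drops below ``ofv_rtol``.
    """
    data = list(data)
    if len(data) < 2:
        raise ValueError("fit_population requires at least 2 patients")
    n_obs_total = sum(len(p.observations) for p in data)
    if n_obs_total < 2:
        raise ValueError("fit_population requires at least 2 observations in total")

    m = (init if init is not None else PopulationModel.from_config(variant)).replace()
    if m.variant != variant:
        m = m.replace(variant=variant)
    warm: dict = {}
    zcache: dict = {}
    history: list = []
    converged = False
    estimates: list = []

    for it in range(1, max_iter + 1):
        names = _free_eta_names(m)
        estimates = []
        for p in data:
            e = fit_individual(
                p,
                m,
                n_starts=n_starts if it == 1 else 1,
                x0=warm.get(p.id),
                with_posterior=variance_correction or estep_samples > 0,
            )
            if estep_samples > 0 and p.observations and len(names):
                if p.id not in zcache:
                    rng = np.random.default_rng(
                        (seed * 1000003 + zlib.crc32(str(p.id).encode())) % 2**31
                    )
                    zcache[p.id] = rng.standard_normal(((estep_samples + 1) // 2, len(names)))
                x_map = np.array([e.etas[n] for n in names])
                # posterior means/variances from importance sampling; the
                # residual-variance update stays on the linearized Laplace
                # path (the exact posterior expectation of 1/pred^2 is
                # unstable where predictions approach zero)
                e.post_mean, e.post_var, _ = _importance_refine(
                    p, m, x_map, e.posterior_cov, zcache[p.id]
                )
            estimates.append(e)
        ofv = float(sum(e.ofv_contribution for e in estimates))
        history.append(ofv)
        if len(history) >= 2 and abs(history[-2] - ofv) <= ofv_rtol * max(abs(ofv), 1.0):
            converged = True
            break
        m, mean_eta = _m_step(m, data, estimates, names, variance_correction, min_sigma)
        # the typical values absorbed exp(mean_eta); the matching warm start
        # for the next E-step is the recentered eta vector
        for p, e in zip(data, estimates):
            warm[p.id] = np.array([e.etas[n] for n in names]) - mean_eta

    return PopulationModelFit(m, history[-1], estimates, converged, len(history), history)


def _m_step(m, data, estimates, names, variance_correction, min_sigma):
    E = np.array(
        [
            e.post_mean if e.post_mean is not None else [e.etas[n] for n in names]
            for e in estimates
        ]
    )
    mean_eta = E.mean(axis=0)
    Ec = E - mean_eta

    new = m.replace()
    for j, name in enumerate(names):
        fld = _ETA_FIELD[name]
        setattr(new, fld, getattr(new, fld) * float(np.exp(mean_eta[j])))
    new.f_u_pop = min(new.f_u_pop, 1.0)

    omega2 = (Ec**2).mean(axis=0)
    post = np.array(
        [
            e.post_var
            if e.post_var is not None
            else (np.diag(e.posterior_cov) if e.posterior_cov is not None else np.zeros(len(names)))
            for e in estimates
        ]
    )
    if variance_correction or any(e.post_var is not None for e in estimates):
        omega2 = omega2 + post.mean(axis=0)
    iiv = dict(new.iiv)
    for j, name in enumerate(names):
        iiv[name] = max(omega_to_cv(float(np.sqrt(omega2[j]))), 0.1)
    new.iiv = iiv

    # residual-variance update: summed squared relative MAP residuals over
    # effective degrees of freedom (n - p_eff, REML-style), where p_eff is
    # the per-patient shrinkage df n_eta - tr(posterior_cov @ prior_precision);
    # p_eff is bounded by the eta count, which keeps the update stable even
    # where predictions are steep or small
    rss = {"total": 0.0, "unbound": 0.0}
    nobs = {"total": 0.0, "unbound": 0.0}
    peff = {"total": 0.0, "unbound": 0.0}
    D = np.diag([1.0 / m.omega(n) ** 2 for n in names]) if names else np.zeros((0, 0))
    for p, e in zip(data, estimates):
        if not p.observations:
            continue
        _, values, is_total, _ = _patient_data(p)
        if e.pred is not None:
            pred = e.pred
        else:
            cl, v, fu = _raw_individual_parameters(m, p.covariates, e.etas)
            pred = np.real(_predict(cl, v, fu, p))
        rel2 = (values - pred) ** 2 / pred**2
        n_i = len(values)
        n_tot = float(np.count_nonzero(is_total))
        if variance_correction and e.posterior_cov is not None and len(names):
            p_i = len(names) - float(np.trace(e.posterior_cov @ D))
        else:
            p_i = 0.0
        rss["total"] += float(rel2[is_total].sum())
        rss["unbound"] += float(rel2[~is_total].sum())
        nobs["total"] += n_tot
        nobs["unbound"] += n_i - n_tot
        peff["total"] += p_i * n_tot / n_i
        peff["unbound"] += p_i * (n_i - n_tot) / n_i
    for ch, fld in (("total", "sigma_total"), ("unbound", "sigma_unbound")):
        if nobs[ch] > 0:
            denom = max(nobs[ch] - peff[ch], 1.0)
            setattr(new, fld, max(100.0 * float(np.sqrt(rss[ch] / denom)), min_sigma))
    return new, mean_eta


def likelihood_ratio_test(ofv_reduced: float, ofv_full: float, extra_params: int) -> float:
    """P-value of the chi-square likelihood-ratio test between nested models.

    ``delta = ofv_reduced - ofv_full`` referred to a chi-square with
    ``extra_params`` degrees of freedom; a negative delta (the richer model
    fits worse) returns p = 1.
    """
    if extra_params < 1:
        raise ValueError("extra_params must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < 0:
        return 1.0
    return float(stats.chi2.sf(delta, extra_params))


@dataclass
class BootstrapSummary:
    """Nonparametric bootstrap summary: per-parameter median and percentile CI."""

    replicates: pd.DataFrame
    median: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_requested: int
    n_failed: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "ci_low": self.ci_low, "ci_high": self.ci_high}
        )


def _fit_params_row(fit: PopulationModelFit) -> dict:
    m = fit.model
    row = {f: getattr(m, f) for f in m.fixed_effect_names}
    row.update({f"iiv_{k}": v for k, v in m.iiv.items() if k in m.eta_names})
    row["sigma_total"] = m.sigma_total
    row["sigma_unbound"] = m.sigma_unbound
    return row


def bootstrap_population(
    data: Sequence[PatientRecord],
    n_boot: int,
    seed: int,
    variant: str = "final",
    init: Optional[PopulationModel] = None,
    ci_level: float = 95.0,
    **fit_kwargs,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the population fit.

    Patients are resampled with replacement (resample size = n patients),
    ``fit_population`` is run on each replicate (initialized at the point
    estimate for speed), non-converged replicates are excluded and counted,
    and per-parameter medians with percentile confidence intervals are
    returned.  A fixed seed gives a bit-identical summary.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    data = list(data)
    rng = np.random.default_rng(seed)
    # replicate fits start at the point estimate and use a relaxed OFV
    # tolerance (percentile CIs are insensitive to the last decimals)
    fit_kwargs.setdefault("ofv_rtol", 1e-3)
    fit_kwargs.setdefault("max_iter", 60)
    if init is None:
        init = fit_population(data, variant=variant, **fit_kwargs).model
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(data), len(data))
        sample = [data[i] for i in idx]
        try:
            fit = fit_population(sample, variant=variant, init=init, **fit_kwargs)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        rows.append(_fit_params_row(fit))
    reps = pd.DataFrame(rows)
    alpha = (100.0 - ci_level) / 2.0
    if len(reps):
        med = reps.median()
        lo = reps.quantile(alpha / 100.0)
        hi = reps.quantile(1.0 - alpha / 100.0)
    else:
        med = lo = hi = pd.Series(dtype=float)
    return BootstrapSummary(reps, med, lo, hi, n_boot, n_failed)


def population_predictions(
    data: Iterable[PatientRecord], m: PopulationModel
) -> tuple[np.ndarray, np.ndarray]:
    """(observed, predicted) pairs at zero etas (population predictions)."""
    obs, pred = [], []
    for p in data:
        if not p.observations:
            continue
        _, values, _, _ = _patient_data(p)
        cl, v, fu = _raw_individual_parameters(m, p.covariates, {})
        obs.append(values)
        pred.append(np.real(_predict(cl, v, fu, p)))
    return np.concatenate(obs), np.concatenate(pred)


def gof_bias_precision(observed, predicted) -> tuple[float, float]:
    """Goodness-of-fit bias and precision of relative prediction errors.

    Bias is the mean percentage error MPE = mean((pred - obs)/obs) * 100;
    precision is the root-mean-square of the same relative errors (RMSE%).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("at least one (observed, predicted) pair is required")
    if np.any(obs <= 0):
        raise ValueError("observed values must be positive")
    rel = (pred - obs) / obs * 100.0
    return float(rel.mean()), float(np.sqrt(np.mean(rel**2)))
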