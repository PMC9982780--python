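# Methods

## Structural model

Drug amount in a single well-stirred compartment with zero-order
(infusion) input and first-order elimination. For an infusion at rate
`R` (mg/h) starting at `t0` with duration `T`, the contribution to the
total concentration is, in closed form,

```
C(t) = (R/CL) * (1 - exp(-k*a)) * exp(-k*b),    k = CL/V,
a = clip(t - t0, 0, T),  b = max(t - t0 - T, 0),
```

and arbitrary schedules superpose linearly. Protein binding is linear:
the unbound concentration is `f_u * C(t)` everywhere, so the unbound
channel inherits the full time course up to a constant factor.

Steady state over one dosing interval `tau` uses the standard
multiple-infusion accumulation formula; continuous infusion is treated
as its steady-state constant level `R0/CL` (`R0` = daily dose / 24 h),
since all targets are evaluated at steady state. Time above a threshold
is solved analytically — the up-crossing by inverting the rising
infusion branch, the down-crossing by inverting the mono-exponential
decay — so PTA carries no time-grid discretization error; a 10,000-point
grid evaluation is retained in the tests as an oracle. "Exceeds" is
strict (`>`) for concentration versus threshold; target fractions use
`>=` (the "=100%" target is evaluated as `>= 100 - 1e-9` because exact
floating-point equality is meaningless).

## Covariate model and variability

Final model: `CL_tot = f_r * CLcr` (CLcr in mL/min/1.73 m2, converted
by 0.06 to L/h), `f_u = f_u_pop * (Alb/alb_ref)^(-ex)`, `V` linear in
weight per 70 kg. The base (covariate-free) model uses allometric
clearance (exponent 0.75) and a constant `f_u`. Renal function may be
derived from serum creatinine with the 2009 CKD-EPI equation, without
the race coefficient (configurable); the eGFR indexed to 1.73 m2 is
used directly without body-surface de-indexing. Covariates are static
per patient.

Random effects are multiplicative lognormal with
`omega^2 = ln(1 + (CV/100)^2)`, applied uniformly (the CV convention for
"lognormal mean +/- SD" is not otherwise pinned down). IIV on the
albumin exponent multiplies the exponent (`ex * exp(eta)`), which keeps
it positive; at the reference albumin it has no effect by construction.
`f_u` is clipped to 1 after random effects (observed unbound fractions
reach the 70% range, so the tail matters). All published typical
values, IIV CVs and residual errors ship in `defaults.yaml`, one block
per model variant, every number overridable; the table also lists a
summary unbound-fraction percentage (25%) for the final model, but the
operative constants here are the covariate-equation values (0.217 at
21.2 g/L) — both are kept in the configuration rather than silently
reconciled.

## Estimation

Individual fitting is MAP Bayesian: minimize the -2 log-posterior

```
sum_j [ ((y_j - f_j)/(sigma_ch * f_j))^2 + ln((sigma_ch * f_j)^2) ]
  + sum_p [ eta_p^2/omega_p^2 + ln omega_p^2 ]
```

with proportional error per channel evaluated at the model prediction
(extended-least-squares convention). Optimization is multi-start
L-BFGS-B (5 perturbed starts by default, eta bounds +/-12) with exact
gradients by complex-step differentiation; an observation preceding any
drug delivery is a hard error (its prediction is structurally zero),
while transient exponential underflow at extreme trial parameters is
floored at 1e-12 mg/L so the optimizer is steered back rather than
crashing.

Population estimation is iterative two-stage (the reference analysis
used a proprietary program whose algorithm is unpublished; ITS with MAP
E-steps is the classical scheme consistent with "maximum a posteriori
Bayesian fitting"):

* **E-step** — MAP-fit every patient (warm-started after the first
  iteration). The MAP mode of each patient's posterior is then refined
  to the posterior *mean* by antithetic importance sampling (default 300
  samples, common random numbers across iterations) around the
  Gauss-Newton Laplace approximation. This matters: the lognormal
  random effects make individual posteriors skewed, the mode is not the
  mean, and updating typical values from modes leaves a material
  asymmetry bias (tens of percent on the albumin exponent in recovery
  experiments). With posterior means the typical-value update
  `ln theta += mean(E[eta])` is the exact EM M-step for lognormally
  distributed individual parameters.
* **M-step** — typical values multiplied by `exp(mean eta)` (etas
  recentered accordingly, including the warm starts — recentering the
  model without recentering the warm starts demonstrably breaks the
  descent property); `omega^2` set to the empirical variance of the
  posterior means plus the mean posterior variance (the EM correction
  that counteracts MAP shrinkage); residual `sigma^2` set REML-style to
  the summed squared relative MAP residuals over effective degrees of
  freedom `n - p_eff`, with `p_eff = n_eta - tr(posterior_cov *
  prior_precision)` per patient. The exact posterior expectation of
  `1/pred^2` is deliberately *not* used for sigma: proportional error is
  ill-behaved where predictions approach zero and that update is
  unstable; the df-corrected form is bounded and recovers the
  generating 42%/35% within a few points in simulation.
* **Convergence** — relative OFV change below 1e-4 (OFV = summed
  individual -2 log-posterior contributions). Non-convergence is
  flagged, never silent. Note the marginal likelihood is unbounded as
  any `omega -> 0` (ln omega^2 diverges), so degenerate datasets (e.g.
  clones of one patient) descend forever at a slowing rate; a coarser
  tolerance is the appropriate stopping rule there.

Model comparison uses the chi-square likelihood-ratio test on OFV
differences; the printed comparisons imply one degree of freedom per
covariate and that is the default when comparing variants. The
bootstrap resamples patients with replacement, refits each replicate
initialized at the point estimate with a relaxed tolerance (1e-3),
excludes and counts non-converged replicates, and reports medians and
2.5/97.5 percentiles. Bias is the mean percentage error
`mean((pred-obs)/obs)*100` and precision the RMSE of the same relative
errors, on population (zero-eta) predictions by default, with an
individual-prediction variant also available — the reference analysis
does not state which convention produced its printed values, so both
are exposed.

## Dosing simulation

Virtual patients are drawn with independent lognormal parameters (no
covariance). Default covariate handling is `fixed_typical` (albumin
21.2 g/L, CLcr 66 mL/min/1.73 m2, weight 70 kg; all variability carried
by the IIV terms), because the published simulation description
mentions only parameter distributions; a `sampled` mode draws covariates
from the cohort distributions for sensitivity analysis. PTA per MIC bin
is the attaining fraction of patients, with a Wilson score interval
(well-behaved near 0/100%) at the configured level. The MIC grid is
arithmetic (bin width 0.0625 mg/L, endpoints inclusive), not a doubling
series. Intermittent infusions default to 0.5 h. For continuous
regimens with fixed covariates the whole simulation has a closed form —
`P(f_u * R0 / CL > threshold)` is a lognormal tail probability — which
the tests use as an independent oracle at 100,000 patients; the
envelope check is a Bonferroni-adjusted Wilson band, simultaneous
across a curve's 64 bins, because a per-bin marginal band is violated by
chance fluctuations of a correct simulator.

### Reproduction of the headline attainment values

With the published final-model parameters, the 12 g/day continuous
value reproduces to within ~6 percentage points (simulated ~32% vs
printed 26%). The 24 g/day value does not: any lognormal, dose-linear
simulation of the published parameters puts the median unbound
steady-state concentration at 24 g/day near 2.9 mg/L and hence PTA near
70%, in both covariate modes, versus the printed 51%. The two printed
values are mutually inconsistent with the published parameter set under
the simulation described (matching both would require a median unbound
level of ~1.0 mg/L at 12 g/day and a log-scale SD near 1.04); the
discrepancy is reported as-is rather than absorbed into parameter
changes.

## Synthetic studies

The generator reproduces the cohort's structure: covariates lognormal,
moment-matched to the printed mean/SD (normal draws would go negative at
these CVs — albumin CV 35%, CLcr CV 64%) and truncated to plausible
ranges by redrawing (albumin 5-60 g/L, CLcr 5-250 mL/min/1.73 m2);
weight lognormal matched to the printed median with a 20% CV (a design
choice; only the median is published); regimens assigned from the
printed mix; treatment courses of 48-96 h. Sampling times are a design
choice (the study reports only "random time points related to dosing"):
sparse patients (1-3 samples) are drawn uniformly after 24 h of
treatment, i.e. at steady state; rich patients (10-28 samples) are
drawn across the whole course from 2 h after the first dose. Rich
sampling deliberately covers the accumulation phase because volume of
distribution is structurally unidentifiable from steady-state samples
of a continuous infusion (a flat line), and 74% of the cohort receives
continuous infusion; the 2 h lower bound avoids near-zero
concentrations where a proportional-only error model is ill-posed (in
practice such samples would be below the quantification limit anyway).
Each sampling time yields a total and an unbound measurement sharing
one true concentration with independent proportional errors per
channel; non-positive draws are redrawn.

What passing recovery tests show — and do not show: at 200 patients
with 12 samples each, all fixed effects are recovered within 10% and
residual errors within a few points, so the estimator is consistent
under the model's own assumptions; at the real design (31 patients, 74%
sparse) clearance and volume are recovered only within ~30%, which is a
statement about the design's information content, not about the
estimator. None of this validates the structural model against real
flucloxacillin data, covariate measurement error, time-varying renal
function, or assay censoring, all of which the generator does not
emulate.

## Problem sizes and seeds

Default problem sizes are the study's own: 31 patients for cohort-scale
experiments, 1000 virtual patients for PTA, 0-4 mg/L MIC grid. The
well-powered recovery experiment uses 200 patients x 12 samples; the
Monte Carlo-versus-analytic cross-check uses 100,000 virtual patients.
Every stochastic entry point takes an explicit seed and is bit-for-bit
reproducible; the population fit additionally uses common random
numbers for its importance-sampling E-step so that iteration paths are
deterministic given the seed.

## Known limitations

* The ITS/EM engine is a point estimator; it does not produce posterior
  distributions (no SAEM/FOCE/full Bayes), and parameter uncertainty
  comes from the bootstrap only.
* IIV variances are mildly underestimated at sparse designs despite the
  posterior-variance correction (visible as downward drift of the
  volume IIV on the 31-patient design), a known property of
  MAP-shrinkage-based schemes.
* Proportional-only residual error is ill-posed near zero
  concentrations; the package guards numerically but a combined
  additive+proportional model is out of scope.
* One compartment, linear binding and linear elimination throughout;
  multi-compartment and saturable-binding structures are out of scope.
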