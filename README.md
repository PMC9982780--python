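# floxpk

Population pharmacokinetics of flucloxacillin in critically ill patients:
a one-compartment model with linear plasma-protein binding, covariate
models on renal function and serum albumin, MAP Bayesian / iterative
two-stage population estimation with nonparametric bootstrap
qualification, and Monte Carlo probability-of-target-attainment (PTA)
dosing simulation.

## The problem

Flucloxacillin is a highly protein-bound beta-lactam used against
Gram-positive infections. Only the unbound fraction is microbiologically
active, and in critically ill patients both protein binding (via
hypoalbuminemia) and clearance (via renal function) vary enormously.
The PK/PD target for efficacy is the fraction of the dosing interval
during which the **unbound** serum concentration exceeds a multiple of
the pathogen's MIC (fT>MIC); for resistant-pathogen coverage the usual
target is unbound concentration above 4xMIC for at least 50% of the
interval.

This package implements the full analysis pipeline for such a study:

* **Structural model** — one-compartment kinetics with zero-order
  (infusion) input and first-order elimination, solved in closed form for
  arbitrary dose-event schedules and at steady state. Total and unbound
  concentrations are linked linearly: `C_u = f_u * C_tot`.
* **Covariate model** —

  ```
  CL_tot = f_r * CLcr                      (f_r = 19, CLcr via CKD-EPI)
  f_u    = f_u,pop * (Alb / 21.2)^(-ex)    (f_u,pop = 0.217, ex = 0.67)
  V      = 330 L * (WT / 70)
  ```

  with independent lognormal inter-individual variability (IIV) on
  `f_r`, `V`, `f_u` and `ex` (CV 71 / 84 / 26 / 88 %) and proportional
  residual errors per measurement channel (42% total, 35% unbound).
* **Estimation** — per-patient maximum a posteriori (MAP) Bayesian fits
  inside an iterative two-stage (ITS/EM) population loop; chi-square
  likelihood-ratio tests on the objective function value (OFV = -2 log L)
  for covariate selection; nonparametric bootstrap for parameter
  confidence intervals; mean-percentage-error bias and RMSE precision
  diagnostics.
* **Dosing simulation** — Monte Carlo virtual populations (default 1000
  patients, lognormal parameters, no covariance), PTA across a MIC grid
  (0-4 mg/L in 0.0625 bins) with Wilson 95% confidence bands, for
  continuous and intermittent (0.5 h infusion) regimens from 4 to
  24 g/day.
* **Synthetic studies** — a generator that emulates the published cohort
  (n = 31; CLcr 66 +/- 42 mL/min/1.73 m2; albumin 23.3 +/- 8.2 g/L;
  median weight 76 kg; 74% sparsely sampled; the printed regimen mix) so
  that every stage is testable without patient data.

## Worked example

```python
import floxpk as fx
from floxpk.pta import SimulationSettings, TargetDefinition, pta_curve, sample_virtual_population

# generate a synthetic cohort with the study's design and fit it
study = fx.generate_study(fx.StudyConfig(), seed=7)
res = fx.PopulationPKModel(study.patients, variant="final").fit()
print(res.summary())

# dosing simulation under the published final model
m = fx.PopulationModel.final()
s = SimulationSettings(n_patients=1000, seed=1)
pop = sample_virtual_population(m, s)
t = TargetDefinition(mic_multiplier=4, fraction_threshold=50.0)
for dose in (12000.0, 24000.0):
    curve = pta_curve(pop, fx.DosingRegimen(dose, "continuous"), t, s)
    print(f"{dose/1000:.0f} g/day continuous: PTA at MIC 0.5 = {curve.pta_at(0.5):.1f}%")
```

prints (abridged):

```
Population PK fit (iterative two-stage, MAP Bayesian E-steps)
  variant: final   patients: 31   observations: 400
  OFV: 144.0   iterations: 100   converged: False

                                estimate
f_r, CL/CLcr                       16.28
V, L/70 kg                         307.2
f_u (at reference albumin)        0.2057
ex (albumin exponent)             0.8378
...

12 g/day continuous: PTA at MIC 0.5 = 33.2%
24 g/day continuous: PTA at MIC 0.5 = 72.5%
```

The fit recovers the generating clearance ratio and volume within the
precision a 31-patient, mostly sparse design allows (`converged: False`
flags that the slow variance-component tail had not fully settled within
the default iteration budget; volume variability is weakly identified
from sparse steady-state samples). The PTA lines say that, under the
final model with covariates at their reference values, only about a
third of virtual patients keep unbound flucloxacillin above 2 mg/L
(4 x the 0.5 mg/L MSSA ECOFF) for half the interval on 12 g/day by
continuous infusion.

A command-line interface mirrors the library:

```bash
floxpk genstudy --n-patients 31 --seed 1 --out study.csv --truth-out truth.json
floxpk fit study.csv --variant final --compare base
floxpk pta --daily-dose 12 --mode continuous --target ft50x4 --seed 1 --out pta.csv
floxpk simulate --cl 75.24 --v 330 --fu 0.217 --daily-dose 12
```

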