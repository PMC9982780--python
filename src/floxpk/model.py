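"""Model / Results front end, statsmodels-style.

``PopulationPKModel`` holds the data and model variant; ``fit()`` runs the
iterative two-stage estimation and returns ``PopulationPKResults`` carrying
the estimated population parameters, OFV, per-patient MAP estimates and
diagnostics, with ``summary()``, ``bootstrap()``, ``lr_test()`` and
simulation methods hanging off it.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import dataset as _dataset
from .covariates import PopulationModel
from .estimation import (
    BootstrapSummary,
    PatientRecord,
    PopulationModelFit,
    bootstrap_population,
    fit_population,
    gof_bias_precision,
    likelihood_ratio_test,
    population_predictions,
    _obs_arrays,
    _predict,
)
from .covariates import _raw_individual_parameters
from .pta import PTAResult, SimulationSettings, TargetDefinition, pta_curve, sample_virtual_population
from .pk import DosingRegimen

__all__ = ["PopulationPKModel", "PopulationPKResults"]


class PopulationPKModel:
    """Population PK model bound to a dataset.

    Parameters
    ----------
    patients : sequence of PatientRecord
        The study data (dosing events, dual-channel observations,
        covariates per patient).
    variant : str
        ``base`` (no covariates), ``egfr_only``, ``albumin_only`` or
        ``final`` (renal-function clearance + albumin binding).
    init : PopulationModel, optional
        Starting values; defaults to the shipped configuration of the
        chosen variant.
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        variant: str = "final",
        init: Optional[PopulationModel] = None,
    ):
        self.patients = list(patients)
        self.variant = variant
        self.init = init

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PopulationPKModel":
        """Build from an event table (NONMEM-convention columns)."""
        return cls(_dataset.frame_to_patients(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PopulationPKModel":
        return cls(_dataset.read_dataset(path), **kwargs)

    @property
    def n_obs(self) -> int:
        return sum(len(p.observations) for p in self.patients)

    def fit(self, **kwargs) -> "PopulationPKResults":
        """Run the iterative two-stage estimation (see
        :func:`floxpk.estimation.fit_population`)."""
        fit = fit_population(self.patients, variant=self.variant, init=self.init, **kwargs)
        return PopulationPKResults(self, fit)

    def simulate_pta(
        self,
        regimen: DosingRegimen,
        target: TargetDefinition,
        settings: SimulationSettings = SimulationSettings(),
        params: Optional[PopulationModel] = None,
    ) -> PTAResult:
        """Monte Carlo PTA curve under ``params`` (default: the variant's
        shipped configuration)."""
        m = params if params is not None else (
            self.init if self.init is not None else PopulationModel.from_config(self.variant)
        )
        population = sample_virtual_population(m, settings)
        return pta_curve(population, regimen, target, settings)


class PopulationPKResults:
    """Estimation results: parameters, OFV, individuals, diagnostics."""

    def __init__(self, model: PopulationPKModel, fit: PopulationModelFit):
        self.model = model
        self._fit = fit
        self._bootstrap: Optional[BootstrapSummary] = None

    # -- estimates -------------------------------------------------------
    @property
    def params(self) -> PopulationModel:
        """The estimated population model."""
        return self._fit.model

    @property
    def ofv(self) -> float:
        return self._fit.ofv

    @property
    def individuals(self):
        return self._fit.individuals

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iterations(self) -> int:
        return self._fit.n_iterations

    @property
    def ofv_history(self):
        return self._fit.ofv_history

    def individual_params_frame(self) -> pd.DataFrame:
        rows = {
            p.id: {
                "cl_total": e.params.cl_total,
                "v": e.params.v,
                "f_u": e.params.f_u,
                **{f"eta_{k}": v for k, v in e.etas.items()},
                "ofv_contribution": e.ofv_contribution,
            }
            for p, e in zip(self.model.patients, self.individuals)
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    # -- inference -------------------------------------------------------
    def bootstrap(self, n_boot: int, seed: int, **fit_kwargs) -> BootstrapSummary:
        """Nonparametric bootstrap (patients resampled with replacement);
        cached so ``summary()`` can report the CIs."""
        self._bootstrap = bootstrap_population(
            self.model.patients,
            n_boot,
            seed,
            variant=self.model.variant,
            init=self.params,
            **fit_kwargs,
        )
        return self._bootstrap

    def lr_test(self, other: "PopulationPKResults", df: Optional[int] = None):
        """Likelihood-ratio test of this (fuller) model against a reduced
        one; ``df`` defaults to the difference in fixed-effect counts.

        Returns (delta_ofv, df, p).
        """
        if df is None:
            df = len(self.params.fixed_effect_names) - len(other.params.fixed_effect_names)
        delta = other.ofv - self.ofv
        return delta, df, likelihood_ratio_test(other.ofv, self.ofv, df)

    def bias_precision(self) -> tuple[float, float]:
        """Population-prediction bias (MPE %) and precision (RMSE %)."""
        obs, pred = population_predictions(self.model.patients, self.params)
        return gof_bias_precision(obs, pred)

    def individual_bias_precision(self) -> tuple[float, float]:
        """Same metrics on individual (MAP) predictions."""
        obs_all, pred_all = [], []
        for p, e in zip(self.model.patients, self.individuals):
            if not p.observations:
                continue
            times, values, is_total = _obs_arrays(p)
            cl, v, fu = _raw_individual_parameters(self.params, p.covariates, e.etas)
            pred_all.append(np.real(_predict(cl, v, fu, p, times, is_total)))
            obs_all.append(values)
        return gof_bias_precision(np.concatenate(obs_all), np.concatenate(pred_all))

    # -- presentation ----------------------------------------------------
    _LABELS = {
        "cl_typ_base": "CL, L/h/70kg^0.75",
        "f_r": "f_r, CL/CLcr",
        "v_typ": "V, L/70 kg",
        "f_u_pop": "f_u (at reference albumin)",
        "ex": "ex (albumin exponent)",
        "iiv_cl": "IIV CL, %",
        "iiv_fr": "IIV f_r, %",
        "iiv_v": "IIV V, %",
        "iiv_fu": "IIV f_u, %",
        "iiv_ex": "IIV ex, %",
        "sigma_total": "Proportional error, total, %",
        "sigma_unbound": "Proportional error, unbound, %",
    }

    def params_frame(self) -> pd.DataFrame:
        """Parameter table: estimate plus bootstrap RSE%, median and 95% CI
        when a bootstrap has been run."""
        m = self.params
        entries = {f: getattr(m, f) for f in m.fixed_effect_names}
        entries.update({f"iiv_{k}": m.iiv[k] for k in m.eta_names if k in m.iiv})
        entries["sigma_total"] = m.sigma_total
        entries["sigma_unbound"] = m.sigma_unbound
        df = pd.DataFrame({"estimate": pd.Series(entries)})
        if self._bootstrap is not None and len(self._bootstrap.replicates):
            reps = self._bootstrap.replicates
            df["rse_pct"] = (reps.std() / df["estimate"].abs() * 100.0).reindex(df.index)
            df["boot_median"] = self._bootstrap.median.reindex(df.index)
            df["ci_low"] = self._bootstrap.ci_low.reindex(df.index)
            df["ci_high"] = self._bootstrap.ci_high.reindex(df.index)
        df.index = [self._LABELS.get(i, i) for i in df.index]
        return df

    def summary(self) -> str:
        """Plain-text report mirroring the usual population-PK parameter
        table layout."""
        lines = [
            "Population PK fit (iterative two-stage, MAP Bayesian E-steps)",
            f"  variant: {self.model.variant}   patients: {len(self.model.patients)}"
            f"   observations: {self.model.n_obs}",
            f"  OFV: {self.ofv:.1f}   iterations: {self.n_iterations}"
            f"   converged: {self.converged}",
            "",
            self.params_frame().to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        try:
            bias, precision = self.bias_precision()
            lines.append("")
            lines.append(
                f"  population-prediction bias (MPE): {bias:.1f}%   "
                f"precision (RMSE): {precision:.1f}%"
            )
        except ValueError:
            pass
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "variant": self.model.variant,
            "ofv": self.ofv,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "params": self.params.to_dict(),
            "individuals": self.individual_params_frame().to_dict(orient="index"),
        }
        if self._bootstrap is not None:
            out["bootstrap"] = {
                "median": self._bootstrap.median.to_dict(),
                "ci_low": self._bootstrap.ci_low.to_dict(),
                "ci_high": self._bootstrap.ci_high.to_dict(),
                "n_requested": self._bootstrap.n_requested,
                "n_failed": self._bootstrap.n_failed,
            }
        return out

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
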