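"""Covariate equations and assembly of individual PK parameters.

The final population model ties total clearance to renal function and the
unbound fraction to serum albumin:

    CL_tot = f_r * CLcr            (CLcr in mL/min/1.73 m2, converted to L/h)
    f_u    = f_u_pop * (Alb / alb_ref) ** (-ex)

with lognormal inter-individual variability (IIV) on ``f_r``, ``V``,
``f_u`` and ``ex``.  The base model has no covariates: clearance scales
allometrically with weight (exponent 0.75) and ``f_u`` is a constant.
Renal function may be supplied directly or derived from serum creatinine
with the 2009 CKD-EPI equation (no race coefficient).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import yaml

from .pk import IndividualParameters

__all__ = [
    "CovariateSet",
    "PopulationModel",
    "VARIANTS",
    "unbound_fraction_from_albumin",
    "clearance_from_clcr",
    "ckd_epi_egfr",
    "allometric_scale",
    "individual_parameters",
    "cv_to_omega",
    "omega_to_cv",
]

#: mL/min -> L/h
ML_MIN_TO_L_H = 0.06

VARIANTS = ("base", "egfr_only", "albumin_only", "final")

# Random-effect names entering each model variant, in canonical order.
_ETA_NAMES = {
    "base": ("cl", "v", "fu"),
    "egfr_only": ("fr", "v", "fu"),
    "albumin_only": ("cl", "v", "fu", "ex"),
    "final": ("fr", "v", "fu", "ex"),
}

# Fixed effects estimated per variant (used for LRT degrees of freedom).
_FIXED_EFFECTS = {
    "base": ("cl_typ_base", "v_typ", "f_u_pop"),
    "egfr_only": ("f_r", "v_typ", "f_u_pop"),
    "albumin_only": ("cl_typ_base", "v_typ", "f_u_pop", "ex"),
    "final": ("f_r", "v_typ", "f_u_pop", "ex"),
}


def cv_to_omega(cv_pct: float) -> float:
    """Lognormal SD omega from a coefficient of variation in percent,
    ``omega^2 = ln(1 + CV^2)``."""
    return float(np.sqrt(np.log1p((cv_pct / 100.0) ** 2)))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega`, in percent."""
    return float(100.0 * np.sqrt(np.expm1(omega**2)))


@dataclass(frozen=True)
class CovariateSet:
    """Per-patient covariates (static values at sampling).

    ``clcr`` (mL/min/1.73 m2) may be given directly or left None and
    resolved from ``serum_creatinine`` (umol/L), ``age`` and ``sex``.
    """

    weight: float
    albumin: float
    clcr: Optional[float] = None
    serum_creatinine: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not self.albumin > 0:
            raise ValueError(f"albumin must be positive, got {self.albumin}")
        if self.clcr is not None and not self.clcr > 0:
            raise ValueError(f"clcr must be positive, got {self.clcr}")

    def resolved_clcr(self) -> float:
        """Creatinine clearance, computing CKD-EPI eGFR when not supplied."""
        if self.clcr is not None:
            return self.clcr
        if self.serum_creatinine is None or self.age is None or self.sex is None:
            raise ValueError(
                "clcr not given and cannot be derived: need serum_creatinine, age and sex"
            )
        return ckd_epi_egfr(self.serum_creatinine, self.age, self.sex)


@dataclass
class PopulationModel:
    """Population-level parameters: typical values, covariate coefficients,
    IIV magnitudes (CV%) and proportional residual errors (CV%) per channel.

    ``iiv`` keys follow the variant's random-effect names:
    ``fr``/``cl``, ``v``, ``fu``, ``ex``.
    """

    variant: str = "final"
    f_u_pop: float = 0.217
    alb_ref: float = 21.2
    ex: float = 0.67
    f_r: float = 19.0
    v_typ: float = 330.0
    cl_typ_base: float = 52.8
    iiv: dict = field(default_factory=lambda: {"fr": 71.0, "v": 84.0, "fu": 26.0, "ex": 88.0})
    sigma_total: float = 42.0
    sigma_unbound: float = 35.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name, val in (
            ("f_u_pop", self.f_u_pop),
            ("alb_ref", self.alb_ref),
            ("v_typ", self.v_typ),
        ):
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not 0 < self.f_u_pop <= 1:
            raise ValueError(f"f_u_pop must lie in (0, 1], got {self.f_u_pop}")
        if any(cv < 0 for cv in self.iiv.values()):
            raise ValueError("IIV CV% entries must be >= 0")
        if self.sigma_total < 0 or self.sigma_unbound < 0:
            raise ValueError("residual error CV% must be >= 0")

    @property
    def eta_names(self) -> tuple[str, ...]:
        return _ETA_NAMES[self.variant]

    @property
    def fixed_effect_names(self) -> tuple[str, ...]:
        return _FIXED_EFFECTS[self.variant]

    def omega(self, eta_name: str) -> float:
        """Lognormal SD of one random effect."""
        return cv_to_omega(self.iiv.get(eta_name, 0.0))

    def sigma(self, channel: str) -> float:
        """Proportional residual SD (as a fraction) for a channel."""
        if channel == "total":
            return self.sigma_total / 100.0
        if channel == "unbound":
            return self.sigma_unbound / 100.0
        raise ValueError(f"unknown channel {channel!r}")

    def replace(self, **kwargs) -> "PopulationModel":
        out = dataclasses.replace(self, **{k: v for k, v in kwargs.items() if k != "iiv"})
        if "iiv" in kwargs:
            out.iiv = dict(kwargs["iiv"])
        else:
            out.iiv = dict(self.iiv)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iiv"] = dict(self.iiv)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationModel":
        return cls(**{k: (dict(v) if k == "iiv" else v) for k, v in d.items()})

    @classmethod
    def from_config(cls, source: str) -> "PopulationModel":
        """Load a named variant from the shipped defaults, or any model from
        a YAML file path."""
        if source in VARIANTS:
            text = resources.files("floxpk").joinpath("defaults.yaml").read_text()
            cfg = yaml.safe_load(text)
            return cls.from_dict(cfg[source])
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if "variant" not in cfg and len(cfg) == 1:
            cfg = next(iter(cfg.values()))
        return cls.from_dict(cfg)

    @classmethod
    def final(cls) -> "PopulationModel":
        return cls.from_config("final")

    @classmethod
    def base(cls) -> "PopulationModel":
        return cls.from_config("base")


def unbound_fraction_from_albumin(
    albumin: float,
    m: PopulationModel,
    eta_fu: float = 0.0,
    eta_ex: float = 0.0,
    clip: bool = True,
):
    """Unbound fraction from the albumin power model
    ``f_u_pop * exp(eta_fu) * (Alb/alb_ref) ** (-ex * exp(eta_ex))``.

    With zero random effects this reduces to the typical-value equation
    (0.217 at the reference albumin 21.2 g/L for the final model).  The
    result is clipped to (0, 1] unless ``clip=False`` (the smooth form is
    needed for derivative-based fitting).
    """
    if not np.all(np.real(albumin) > 0):
        raise ValueError(f"albumin must be positive, got {albumin}")
    # log-space form; the exponent is clipped far outside the physical range
    # so that extreme trial etas during optimization cannot overflow
    z = eta_fu - m.ex * np.exp(eta_ex) * np.log(albumin / m.alb_ref)
    z = np.where(np.real(z) > 300.0, 300.0, np.where(np.real(z) < -300.0, -300.0, z))
    fu = m.f_u_pop * np.exp(z)
    if clip:
        return float(min(np.real(fu), 1.0))
    return fu


def clearance_from_clcr(clcr: float, m: PopulationModel, eta_fr: float = 0.0):
    """Total clearance proportional to creatinine clearance,
    ``f_r * exp(eta_fr) * CLcr``, converted from mL/min to L/h."""
    if not np.all(np.real(clcr) > 0):
        raise ValueError(f"clcr must be positive, got {clcr}")
    return m.f_r * np.exp(eta_fr) * clcr * ML_MIN_TO_L_H


def ckd_epi_egfr(serum_creatinine: float, age: float, sex: str) -> float:
    """2009 CKD-EPI estimated GFR, mL/min/1.73 m2 (no race coefficient).

    ``serum_creatinine`` in umol/L (converted internally to mg/dL by /88.4).
    """
    if not serum_creatinine > 0:
        raise ValueError(f"serum_creatinine must be positive, got {serum_creatinine}")
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    sex = str(sex).lower()
    if sex in ("f", "female", "2"):
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex in ("m", "male", "1"):
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"sex must identify male or female, got {sex!r}")
    scr = serum_creatinine / 88.4
    ratio = scr / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age * sex_factor
    return float(egfr)


def allometric_scale(value_per_70kg: float, weight: float, exponent: float):
    """Scale a per-70-kg typical value to ``weight``:
    ``value * (weight/70) ** exponent``."""
    if not np.all(np.real(weight) > 0):
        raise ValueError(f"weight must be positive, got {weight}")
    return value_per_70kg * (weight / 70.0) ** exponent


def _raw_individual_parameters(
    m: PopulationModel, c: CovariateSet, etas: Mapping[str, float]
):
    """(cl, v, fu) before clipping; values may be complex under complex-step
    perturbed etas.  Etas for parameters with zero IIV are forced to 0."""
    e = {name: (etas.get(name, 0.0) if m.iiv.get(name, 0.0) > 0 else 0.0) for name in m.eta_names}
    v = allometric_scale(m.v_typ, c.weight, 1.0) * np.exp(e.get("v", 0.0))
    if m.variant in ("final", "egfr_only"):
        cl = clearance_from_clcr(c.resolved_clcr(), m, e.get("fr", 0.0))
    else:
        cl = allometric_scale(m.cl_typ_base, c.weight, 0.75) * np.exp(e.get("cl", 0.0))
    if m.variant in ("final", "albumin_only"):
        fu = unbound_fraction_from_albumin(
            c.albumin, m, e.get("fu", 0.0), e.get("ex", 0.0), clip=False
        )
    else:
        fu = m.f_u_pop * np.exp(e.get("fu", 0.0))
    return cl, v, fu


def individual_parameters(
    m: PopulationModel, c: CovariateSet, etas: Optional[Mapping[str, float]] = None
) -> IndividualParameters:
    """Assemble one patient's PK parameters from population values,
    covariates and lognormal random effects.

    Final variant: ``CL = f_r e^eta CLcr``, ``V = v_typ (wt/70) e^eta``,
    ``f_u`` from the albumin equation.  Base variant: allometric clearance
    (exponent 0.75) and a covariate-free ``f_u``.  ``f_u`` is clipped to 1.
    """
    cl, v, fu = _raw_individual_parameters(m, c, etas or {})
    return IndividualParameters(float(np.real(cl)), float(np.real(v)), min(float(np.real(fu)), 1.0))
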