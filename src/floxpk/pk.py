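"""One-compartment infusion kinetics with linear plasma-protein binding.

Closed-form solutions for zero-order (constant-rate) infusions into a single
well-stirred compartment with first-order elimination.  Total and unbound
drug are linked by a constant unbound fraction ``f_u`` (linear binding), so
the unbound concentration is ``f_u`` times the total concentration
everywhere.  All times are hours since the start of the first dose,
concentrations mg/L, amounts mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IndividualParameters",
    "DoseEvent",
    "DosingRegimen",
    "ConcentrationProfile",
    "elimination_rate",
    "concentration_total",
    "concentration_profile",
    "steady_state_profile",
    "fraction_time_above",
]


@dataclass(frozen=True)
class IndividualParameters:
    """PK parameters of one (real or virtual) patient.

    Attributes
    ----------
    cl_total : float
        Total drug clearance, L/h.
    v : float
        Volume of distribution, L.
    f_u : float
        Unbound (free) fraction of drug in serum, dimensionless in (0, 1].
    """

    cl_total: float
    v: float
    f_u: float

    def __post_init__(self) -> None:
        if not self.cl_total > 0:
            raise ValueError(f"cl_total must be positive, got {self.cl_total}")
        if not self.v > 0:
            raise ValueError(f"v must be positive, got {self.v}")
        if not 0 < self.f_u <= 1:
            raise ValueError(f"f_u must lie in (0, 1], got {self.f_u}")

    @property
    def k_el(self) -> float:
        """First-order elimination rate constant CL/V, 1/h."""
        return self.cl_total / self.v

    @property
    def half_life(self) -> float:
        """Elimination half-life ln(2)/k, h."""
        return float(np.log(2.0) / self.k_el)


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion: ``amount`` mg over ``duration`` h
    starting at ``start_time`` h after the first dose."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class DosingRegimen:
    """A repeating dosing schedule defined by its daily dose.

    ``continuous`` delivers ``daily_dose`` mg at a constant rate over each
    24 h; ``intermittent`` delivers ``daily_dose * interval / 24`` mg per
    administration as a short infusion (default 0.5 h) every ``interval`` h.
    """

    daily_dose: float
    mode: str = "continuous"
    interval: float = 24.0
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if not self.daily_dose > 0:
            raise ValueError(f"daily_dose must be positive, got {self.daily_dose}")
        if self.mode not in ("continuous", "intermittent"):
            raise ValueError(f"mode must be 'continuous' or 'intermittent', got {self.mode!r}")
        if self.mode == "continuous":
            object.__setattr__(self, "interval", 24.0)
            object.__setattr__(self, "infusion_duration", 24.0)
        else:
            if not 0 < self.infusion_duration <= self.interval <= 24:
                raise ValueError(
                    "intermittent regimen requires 0 < infusion_duration <= interval <= 24, "
                    f"got duration={self.infusion_duration}, interval={self.interval}"
                )
            n = 24.0 / self.interval
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"24 h must be an integer multiple of the interval, got {self.interval}")

    @property
    def dose_per_administration(self) -> float:
        """mg delivered per infusion (the whole daily dose for continuous)."""
        if self.mode == "continuous":
            return self.daily_dose
        return self.daily_dose * self.interval / 24.0

    @property
    def infusion_rate(self) -> float:
        """mg/h while the pump runs."""
        return self.dose_per_administration / self.infusion_duration

    def dose_events(self, duration: float) -> list[DoseEvent]:
        """Expand the regimen into explicit dose events covering ``duration`` h."""
        if self.mode == "continuous":
            n_days = int(np.ceil(duration / 24.0))
            return [DoseEvent(24.0 * i, self.daily_dose, 24.0) for i in range(max(n_days, 1))]
        n = int(np.ceil(duration / self.interval))
        amt = self.dose_per_administration
        return [DoseEvent(self.interval * i, amt, self.infusion_duration) for i in range(max(n, 1))]


@dataclass
class ConcentrationProfile:
    """Paired total/unbound concentration-time course."""

    times: np.ndarray
    total: np.ndarray
    unbound: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.unbound = np.asarray(self.unbound, dtype=float)
        if not (len(self.times) == len(self.total) == len(self.unbound)):
            raise ValueError("times, total and unbound must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def elimination_rate(p: IndividualParameters) -> float:
    """First-order elimination rate constant ``k = CL/V``, 1/h."""
    return p.cl_total / p.v


def _superposition_design(doses: Sequence[DoseEvent], t: np.ndarray):
    """Parameter-independent pieces of the superposition sum.

    For each dose and time the closed-form contribution is
    ``(rate/CL) * (1 - e^{-k a}) * e^{-k b}`` with ``a`` the elapsed infusion
    time (clipped to the duration) and ``b`` the post-infusion decay time;
    returns (rates, a, b) with a and b of shape (n_doses, n_times).
    """
    starts = np.array([d.start_time for d in doses])[:, None]
    durs = np.array([d.duration for d in doses])[:, None]
    rates = np.array([d.rate for d in doses])[:, None]
    dt = t[None, :] - starts
    a = np.clip(dt, 0.0, durs)
    b = np.maximum(dt - durs, 0.0)
    return rates, a, b


def _conc_from_design(cl, v, rates, a, b):
    k = cl / v
    return np.sum(rates * (np.exp(-k * b) - np.exp(-k * (a + b))), axis=0) / cl


def _conc_total_raw(cl, v, doses: Sequence[DoseEvent], t):
    """Total concentration by superposition of closed-form infusion branches.

    ``cl`` and ``v`` may be complex (used for complex-step differentiation);
    ``t`` may be a scalar or array of real times.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    rates, a, b = _superposition_design(doses, t_arr)
    c = _conc_from_design(cl, v, rates, a, b)
    if np.ndim(t) == 0:
        return c[0]
    return c


def concentration_total(p: IndividualParameters, doses: Iterable[DoseEvent], t):
    """Total serum concentration (mg/L) at time(s) ``t`` under ``doses``.

    Linear superposition of zero-order infusions: during an infusion the
    contribution rises as ``(R/CL)(1 - e^{-kt})``; afterwards it decays
    mono-exponentially.
    """
    doses = list(doses)
    out = _conc_total_raw(p.cl_total, p.v, doses, t)
    if out.ndim == 0:
        return float(out)
    return out.astype(float)


def concentration_profile(
    p: IndividualParameters, doses: Iterable[DoseEvent], times
) -> ConcentrationProfile:
    """Evaluate total and unbound concentrations on a time grid."""
    total = concentration_total(p, doses, times)
    total = np.atleast_1d(np.asarray(total, dtype=float))
    return ConcentrationProfile(np.asarray(times, dtype=float), total, p.f_u * total)


def _ss_levels(cl, v, r: DosingRegimen):
    """Steady-state trough (interval start) and end-of-infusion peak of the
    *total* concentration for an intermittent regimen."""
    k = cl / v
    tau = r.interval
    tinf = r.infusion_duration
    rate = r.infusion_rate
    a = rate / cl
    denom = -np.expm1(-k * tau)
    peak = a * (-np.expm1(-k * tinf)) / denom
    trough = peak * np.exp(-k * (tau - tinf))
    return trough, peak, a, k


def steady_state_profile(
    p: IndividualParameters, r: DosingRegimen, n_times: int = 200
) -> ConcentrationProfile:
    """Closed-form steady-state profile over one dosing interval [0, tau).

    Continuous mode is a flat line at ``Css = R0/CL`` with ``R0`` the daily
    dose divided by 24 h.  Intermittent mode uses the multiple-infusion
    accumulation formula; the infusion starts at interval time 0.
    """
    if n_times < 2:
        raise ValueError("n_times must be >= 2")
    if r.mode == "continuous":
        css = (r.daily_dose / 24.0) / p.cl_total
        times = np.linspace(0.0, 24.0, n_times, endpoint=False)
        total = np.full(n_times, css)
        return ConcentrationProfile(times, total, p.f_u * total)
    times = np.linspace(0.0, r.interval, n_times, endpoint=False)
    total = _ss_total_at(p.cl_total, p.v, r, times)
    return ConcentrationProfile(times, np.asarray(total, float), p.f_u * np.asarray(total, float))


def _ss_total_at(cl, v, r: DosingRegimen, t):
    """Steady-state total concentration at interval time(s) ``t`` in [0, tau)."""
    t = np.asarray(t, dtype=float)
    trough, peak, a, k = _ss_levels(cl, v, r)
    tinf = r.infusion_duration
    during = a + (trough - a) * np.exp(-k * t)
    after = peak * np.exp(-k * (t - tinf))
    return np.where(t <= tinf, during, after)


def _ss_fraction_above(cl, v, f_u, r: DosingRegimen, threshold) -> np.ndarray:
    """Vectorized percent of the steady-state dosing interval with *unbound*
    concentration strictly above ``threshold``.

    ``cl``, ``v``, ``f_u`` and ``threshold`` broadcast as numpy arrays.
    Crossing times are solved analytically on both branches, so the result
    carries no grid-resolution error.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    f_u = np.asarray(f_u, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    cl, v, f_u, thr = np.broadcast_arrays(cl, v, f_u, thr)

    if r.mode == "continuous":
        u = f_u * (r.daily_dose / 24.0) / cl
        return np.where(thr <= 0, 100.0, np.where(u > thr, 100.0, 0.0))

    tau = r.interval
    tinf = r.infusion_duration
    trough, peak, a, k = _ss_levels(cl, v, r)
    u0 = f_u * trough     # interval-start level (equals the level at tau)
    umax = f_u * peak     # end-of-infusion level
    ua = f_u * a          # infusion-branch asymptote, > umax when tinf < tau

    with np.errstate(divide="ignore", invalid="ignore"):
        # up-crossing on the rising branch u(t) = ua + (u0 - ua) e^{-kt}
        ratio_up = np.clip((ua - thr) / (ua - u0), 1e-300, 1.0)
        t_up = np.where(thr > u0, -np.log(ratio_up) / k, 0.0)
        # down-crossing on the decay branch u(t) = umax e^{-k(t - tinf)}
        t_down = np.where(thr > 0, tinf + np.log(umax / np.maximum(thr, 1e-300)) / k, tau)
    t_down = np.minimum(t_down, tau)
    frac = 100.0 * (t_down - t_up) / tau
    frac = np.where(thr < umax, frac, 0.0)
    frac = np.where(thr <= 0, 100.0, frac)
    return np.clip(frac, 0.0, 100.0)


def fraction_time_above(
    p: IndividualParameters, r: DosingRegimen, threshold: float
) -> float:
    """Percent of the steady-state dosing interval with unbound concentration
    strictly exceeding ``threshold`` mg/L (the fT>MIC machinery).

    Computed in closed form: the up-crossing is located by inverting the
    rising infusion branch and the down-crossing by inverting the
    mono-exponential decay.  Continuous infusions are all-or-nothing (100 if
    the flat unbound steady-state level exceeds the threshold, else 0).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return float(_ss_fraction_above(p.cl_total, p.v, p.f_u, r, threshold))
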