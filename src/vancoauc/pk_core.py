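"""Closed-form one-compartment intermittent-infusion pharmacokinetics.

All quantities use a single internal unit canon: doses in mg, volumes in L,
times in h, concentrations in mg/L (numerically identical to ug/mL).  Doses
expressed in g must be converted at the I/O boundary; nothing in this module
rescales units.

The three closed forms exposed here are the backbone of the nomogram method:

* ``cpeak_first_1c`` -- concentration 1 h after the end of the *first*
  infusion (the sampling time at which the apparent volume of distribution
  is read off);
* ``ctrough_ss_1c`` -- steady-state trough immediately before a dose under
  a fixed maintenance regimen;
* ``auc24_1c`` -- 24-h area under the curve at steady state, which for
  linear kinetics is simply (daily dose) / (Ke * Vd).

``one_comp_profile`` generates the full superposed concentration-time curve
by summing single-infusion solutions; it serves as the internal numerical
oracle against which the closed forms are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PEAK_SAMPLING_LAG_H",
    "Concentration",
    "DosingRegimen",
    "OneCompParams",
    "auc24_1c",
    "cpeak_first_1c",
    "ctrough_ss_1c",
    "one_comp_profile",
    "regimen_dose_times",
]

#: Hours between the end of the first infusion and the peak blood draw.
#: The peak closed form hard-codes this lag; the profile generator accepts
#: arbitrary sampling times for records drawn at 0.5-2 h.
PEAK_SAMPLING_LAG_H = 1.0


class DomainError(ValueError):
    """Raised when a pharmacokinetic quantity is outside its valid domain."""


@dataclass(frozen=True)
class DosingRegimen:
    """An intermittent-infusion vancomycin regimen.

    Parameters
    ----------
    first_dose : float
        Loading dose (mg).
    maintenance_dose : float
        Repeated maintenance dose (mg).
    tau : float
        Dosing interval (h).
    t_in : float
        Infusion duration of maintenance doses (h); must be < tau.
    t_in_first : float, optional
        Infusion duration of the first dose (h).  Dose-size rules make the
        loading infusion longer than maintenance infusions, so both are
        carried; defaults to ``t_in``.
    """

    first_dose: float
    maintenance_dose: float
    tau: float
    t_in: float
    t_in_first: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.t_in_first == 0.0:
            object.__setattr__(self, "t_in_first", self.t_in)
        for name in ("first_dose", "maintenance_dose", "tau", "t_in", "t_in_first"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise DomainError(f"{name} must be positive and finite, got {v!r}")
        if self.t_in >= self.tau:
            raise DomainError(
                f"infusion time ({self.t_in} h) must be shorter than the "
                f"dosing interval ({self.tau} h)"
            )

    @property
    def daily_dose(self) -> float:
        """Maintenance dose delivered per 24 h (mg)."""
        return self.maintenance_dose * 24.0 / self.tau


@dataclass(frozen=True)
class OneCompParams:
    """One-compartment parameters: elimination rate constant and volume."""

    ke: float  # 1/h
    vd: float  # L

    def __post_init__(self) -> None:
        if not (self.ke > 0 and math.isfinite(self.ke)):
            raise DomainError(f"ke must be positive, got {self.ke!r}")
        if not (self.vd > 0 and math.isfinite(self.vd)):
            raise DomainError(f"vd must be positive, got {self.vd!r}")

    @property
    def cl(self) -> float:
        """Clearance Ke*Vd (L/h)."""
        return self.ke * self.vd


@dataclass(frozen=True)
class Concentration:
    """A drug concentration in mg/L (identical to ug/mL)."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise DomainError(f"concentration must be >= 0, got {self.value!r}")


def _one_minus_exp_neg(x: float) -> float:
    # (1 - e^{-x}); -expm1 avoids the cancellation the naive form suffers
    # for Ke*t below ~1e-10.
    return -math.expm1(-x)


def cpeak_first_1c(regimen: DosingRegimen, params: OneCompParams) -> Concentration:
    """First-dose peak concentration, sampled 1 h after the infusion ends.

    C = FD / (Ke*Vd*t_in) * (1 - e^{-Ke*t_in}) * e^{-Ke*1}

    In the zero-elimination limit this tends to FD/Vd, the dilution of the
    full dose into the distribution volume.
    """
    ke, vd = params.ke, params.vd
    t_in = regimen.t_in_first
    infusion_factor = _one_minus_exp_neg(ke * t_in) / (ke * vd * t_in)
    value = regimen.first_dose * infusion_factor * math.exp(-ke * PEAK_SAMPLING_LAG_H)
    return Concentration(value)


def ctrough_ss_1c(regimen: DosingRegimen, params: OneCompParams) -> Concentration:
    """Steady-state trough concentration immediately before a dose.

    C = MD / (Ke*Vd*t_in) * (1 - e^{-Ke*t_in}) / (1 - e^{-Ke*tau})
        * e^{-Ke*(tau - t_in)}

    The middle ratio is the steady-state accumulation factor; as tau grows
    it tends to 1 and the expression collapses to the single-dose trough.
    """
    ke, vd = params.ke, params.vd
    t_in, tau = regimen.t_in, regimen.tau
    value = (
        regimen.maintenance_dose
        / (ke * vd * t_in)
        * _one_minus_exp_neg(ke * t_in)
        / _one_minus_exp_neg(ke * tau)
        * math.exp(-ke * (tau - t_in))
    )
    return Concentration(value)


def auc24_1c(regimen: DosingRegimen, params: OneCompParams) -> float:
    """Steady-state 24-h AUC (mg*h/L): daily maintenance dose / clearance.

    AUC24 = MD / (Ke*Vd) * 24 / tau
    """
    cl = params.cl
    if cl <= 0:
        raise DomainError("clearance must be positive")
    return regimen.maintenance_dose / cl * 24.0 / regimen.tau


def regimen_dose_times(
    regimen: DosingRegimen, t_end: float
) -> list[tuple[float, float, float]]:
    """Dose events (start time, amount mg, infusion duration h) on [0, t_end).

    The first dose starts at t=0; maintenance doses start at tau, 2*tau, ...
    """
    doses = [(0.0, regimen.first_dose, regimen.t_in_first)]
    t = regimen.tau
    while t < t_end:
        doses.append((t, regimen.maintenance_dose, regimen.t_in))
        t += regimen.tau
    return doses


def one_comp_profile(
    doses: list[tuple[float, float, float]],
    params: OneCompParams,
    times: np.ndarray,
) -> np.ndarray:
    """Superposed one-compartment concentration profile.

    Each dose (t0, amount, t_in) contributes the analytic zero-order
    infusion solution

        C(t) = R0/(Ke*Vd) * (1 - e^{-Ke*(t-t0)})              t0 <= t <= t0+t_in
        C(t) = C(t0+t_in) * e^{-Ke*(t-t0-t_in)}               t > t0+t_in

    with R0 = amount/t_in, and the contributions add by linearity.
    """
    times = np.asarray(times, dtype=float)
    ke, vd = params.ke, params.vd
    conc = np.zeros_like(times)
    for t0, amount, t_in in doses:
        rel = times - t0
        r0 = amount / t_in
        during = (rel >= 0) & (rel <= t_in)
        after = rel > t_in
        conc[during] += r0 / (ke * vd) * -np.expm1(-ke * rel[during])
        c_end = r0 / (ke * vd) * _one_minus_exp_neg(ke * t_in)
        conc[after] += c_end * np.exp(-ke * (rel[after] - t_in))
    return conc
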