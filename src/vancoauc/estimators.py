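"""Inverse problems: Vd,app, Ke from trough, peak/trough fits, MAP Bayes.

Four estimators, in increasing order of machinery:

* :func:`vd_app` -- the apparent distribution volume, first dose divided by
  the first peak concentration.  A deliberate simplification: because the
  peak is drawn ~1 h after the infusion ends (post-distribution, after some
  elimination), Vd,app systematically overestimates the true Vd, and more
  so at high clearance.
* :func:`solve_ke_from_trough` -- inverts the steady-state trough closed
  form for Ke at known (assumed) Vd, using the strict monotonicity of the
  trough in Ke.
* :func:`fit_1c_peak_trough` -- joint (Ke, Vd) from one peak and one
  trough.  Two equations, two unknowns: the peak/trough ratio is free of
  Vd, so Ke is a 1-D root and Vd follows from the peak equation.  This is
  exact least squares whenever both equations can be satisfied exactly.
* :func:`map_estimate_2c` -- maximum-a-posteriori two-compartment fit
  combining a population prior with a patient's measured concentrations,
  the standard Bayesian TDM computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from vancoauc.pk_core import (
    DomainError,
    DosingRegimen,
    OneCompParams,
    auc24_1c,
    cpeak_first_1c,
    ctrough_ss_1c,
)
from vancoauc.twocomp import TwoCompParams, conc_2c

logger = logging.getLogger(__name__)

__all__ = [
    "KE_BRACKET",
    "FitResult",
    "MapPrior",
    "NonConvergenceError",
    "fit_1c_peak_trough",
    "map_estimate_2c",
    "solve_ke_from_trough",
    "vd_app",
]

#: Ke search bracket (1/h): half-lives from ~8 minutes to ~290 days, which
#: covers any clinically plausible vancomycin elimination.  Targets that
#: fall outside are treated as data errors, never extrapolated.
KE_BRACKET = (1e-4, 5.0)


class NonConvergenceError(RuntimeError):
    """An inverse problem had no solution in range or the solver failed."""


def vd_app(first_dose: float, cpeak_first: float) -> float:
    """Apparent volume of distribution: first dose / first peak (L).

    Both arguments must be positive; dose in mg, concentration in mg/L.
    """
    if not first_dose > 0:
        raise DomainError(f"first_dose must be > 0, got {first_dose!r}")
    if not cpeak_first > 0:
        raise DomainError(f"cpeak_first must be > 0, got {cpeak_first!r}")
    return first_dose / cpeak_first


def _trough_at(regimen: DosingRegimen, ke: float, vd: float) -> float:
    return ctrough_ss_1c(regimen, OneCompParams(ke=ke, vd=vd)).value


def solve_ke_from_trough(
    regimen: DosingRegimen,
    vd: float,
    ctrough_ss: float,
    bracket: tuple[float, float] = KE_BRACKET,
    xtol: float = 1e-14,
) -> float:
    """Solve the steady-state trough equation for Ke at fixed Vd (1/h).

    The trough is strictly decreasing in Ke (faster elimination lowers both
    the accumulation factor and the end-of-interval decay), so the root is
    unique; it is found by bracketed root-finding to |residual| < 1e-10 mg/L.
    """
    if not vd > 0:
        raise DomainError(f"vd must be > 0, got {vd!r}")
    if not ctrough_ss > 0:
        raise DomainError(f"ctrough_ss must be > 0, got {ctrough_ss!r}")
    lo, hi = bracket
    c_lo = _trough_at(regimen, lo, vd)
    c_hi = _trough_at(regimen, hi, vd)
    if not (c_hi <= ctrough_ss <= c_lo):
        raise NonConvergenceError(
            f"trough {ctrough_ss} mg/L outside the attainable interval "
            f"[{c_hi:.3g}, {c_lo:.3g}] mg/L for Ke in [{lo}, {hi}] 1/h"
        )
    ke = optimize.brentq(
        lambda k: _trough_at(regimen, k, vd) - ctrough_ss,
        lo,
        hi,
        xtol=xtol,
        rtol=8.9e-16,
    )
    residual = _trough_at(regimen, ke, vd) - ctrough_ss
    if abs(residual) > 1e-10:
        raise NonConvergenceError(f"trough residual {residual:.2e} mg/L too large")
    return float(ke)


@dataclass(frozen=True)
class FitResult:
    """Outcome of an individual-parameter fit."""

    params: object  # OneCompParams or TwoCompParams
    objective: float
    converged: bool
    auc_24: float  # mg*h/L
    cl_estimate: float  # L/h
    n_obs: int = 2


def fit_1c_peak_trough(
    regimen: DosingRegimen,
    cpeak_first: float,
    ctrough_ss: float,
    bracket: tuple[float, float] = KE_BRACKET,
) -> FitResult:
    """Least-squares one-compartment (Ke, Vd) from a peak and a trough.

    The ratio Cpeak,first/Ctrough,ss does not involve Vd, so Ke is the root
    of a strictly monotone 1-D function (the ratio increases with Ke: the
    trough decays for tau - t_in hours versus 1 h for the peak).  Vd is then
    recovered from the peak equation.  With two observations and two
    parameters the residuals vanish at the solution, making this the exact
    least-squares optimum; a generic optimizer is retained as fallback for
    targets on the bracket edge.
    """
    if not cpeak_first > 0 or not ctrough_ss > 0:
        raise DomainError("both concentrations must be > 0")
    if cpeak_first <= ctrough_ss:
        raise NonConvergenceError(
            f"peak ({cpeak_first}) must exceed trough ({ctrough_ss}) for an "
            "intermittent regimen with elimination"
        )
    target = cpeak_first / ctrough_ss

    def ratio(ke: float) -> float:
        p = OneCompParams(ke=ke, vd=1.0)  # Vd cancels in the ratio
        return cpeak_first_1c(regimen, p).value / ctrough_ss_1c(regimen, p).value

    lo, hi = bracket
    r_lo, r_hi = ratio(lo), ratio(hi)
    if r_lo <= target <= r_hi:
        ke = float(optimize.brentq(lambda k: ratio(k) - target, lo, hi, xtol=1e-12))
        vd = (
            cpeak_first_1c(regimen, OneCompParams(ke=ke, vd=1.0)).value / cpeak_first
        )
        params = OneCompParams(ke=ke, vd=vd)
        resid = np.array(
            [
                cpeak_first_1c(regimen, params).value - cpeak_first,
                ctrough_ss_1c(regimen, params).value - ctrough_ss,
            ]
        )
        return FitResult(
            params=params,
            objective=float(resid @ resid),
            converged=True,
            auc_24=auc24_1c(regimen, params),
            cl_estimate=params.cl,
        )

    # Fallback: concentration pair not exactly representable within the Ke
    # bracket; minimize squared residuals over (log Ke, log Vd).
    logger.info("peak/trough ratio %.3g outside exact-solve range; optimizing", target)

    def objective(x: np.ndarray) -> float:
        p = OneCompParams(ke=math.exp(x[0]), vd=math.exp(x[1]))
        return (cpeak_first_1c(regimen, p).value - cpeak_first) ** 2 + (
            ctrough_ss_1c(regimen, p).value - ctrough_ss
        ) ** 2

    res = optimize.minimize(
        objective,
        x0=[math.log(0.1), math.log(50.0)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    ke = math.exp(res.x[0])
    if not res.success or not (lo <= ke <= hi):
        raise NonConvergenceError(
            f"one-compartment fit failed for peak={cpeak_first}, "
            f"trough={ctrough_ss}: {res.message}"
        )
    params = OneCompParams(ke=ke, vd=math.exp(res.x[1]))
    return FitResult(
        params=params,
        objective=float(res.fun),
        converged=True,
        auc_24=auc24_1c(regimen, params),
        cl_estimate=params.cl,
    )


# --- MAP Bayesian two-compartment estimator ------------------------------

@dataclass(frozen=True)
class MapPrior:
    """Population prior for MAP estimation.

    ``typical`` holds the typical-value parameters (usually evaluated at
    the patient's creatinine clearance); ``omega`` the log-scale prior SDs
    for (cl, vss, k21).  An omega of 0 pins the parameter at its typical
    value; ``math.inf`` makes it a flat (uninformative) coordinate.  k12 is
    always fixed at its typical value, mirroring the population model.

    The residual model gives observation-level variance
    sigma^2 = (prop * c_obs)^2 + add^2 (kind selects which terms are
    active); weights are anchored at the observed concentration so the
    objective stays a genuine least squares.
    """

    typical: TwoCompParams
    omega: tuple[float, float, float] = (0.3, 0.3, 0.3)
    residual_kind: str = "proportional"  # proportional | additive | combined
    residual_prop: float = 0.20
    residual_add: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omega):
            raise DomainError("omega SDs must be >= 0")
        if self.residual_kind not in ("proportional", "additive", "combined"):
            raise DomainError(f"unknown residual kind {self.residual_kind!r}")
        prop = self.residual_prop if self.residual_kind != "additive" else 0.0
        add = self.residual_add if self.residual_kind != "proportional" else 0.0
        if prop <= 0 and add <= 0:
            raise DomainError("at least one residual error component must be > 0")

    def obs_sd(self, c_obs: float) -> float:
        prop = self.residual_prop if self.residual_kind != "additive" else 0.0
        add = self.residual_add if self.residual_kind != "proportional" else 0.0
        return math.sqrt((prop * c_obs) ** 2 + add**2)


def map_estimate_2c(
    doses: Sequence[tuple[float, float, float]],
    observations: Sequence[tuple[float, float]],
    prior: MapPrior,
    regimen: DosingRegimen | None = None,
    n_restarts: int = 0,
    seed: int = 0,
) -> FitResult:
    """MAP two-compartment fit from timed concentration observations.

    Minimizes the (-2 log) posterior

        sum_i ((c_obs,i - c_pred,i) / sigma_i)^2
        + sum_p (log(P_p / TV_p) / omega_p)^2

    over log-scale (CL, Vss, k21); k12 stays at its typical value.  The
    optimization starts from the typical values (deterministic); optional
    random restarts guard against local minima and the best objective wins.
    AUC_24 is clearance-based: daily maintenance dose / CL_MAP (equivalent
    to the steady-state profile integral for linear kinetics), so a
    ``regimen`` is required for the AUC to be reported.
    """
    if len(observations) < 1:
        raise DomainError("need at least one timed concentration observation")
    obs_t = np.array([t for t, _c in observations], dtype=float)
    obs_c = np.array([c for _t, c in observations], dtype=float)
    if np.any(obs_c <= 0):
        raise DomainError("observed concentrations must be > 0")
    sd = np.array([prior.obs_sd(c) for c in obs_c])
    tv = prior.typical
    log_tv = np.log([tv.cl, tv.vss, tv.k21])
    omega = np.asarray(prior.omega, dtype=float)
    free = omega > 1e-8  # omega ~ 0 pins the coordinate at its typical value
    penalized = free & np.isfinite(omega)

    def unpack(x_free: np.ndarray) -> TwoCompParams:
        x = np.zeros(3)
        x[free] = x_free
        cl, vss, k21 = np.exp(log_tv + x)
        return TwoCompParams(cl=cl, vss=vss, k12=tv.k12, k21=k21)

    def objective(x_free: np.ndarray) -> float:
        if np.any(np.abs(x_free) > 20):
            return 1e12
        p = unpack(x_free)
        pred = conc_2c(doses, p, obs_t)
        if np.any(~np.isfinite(pred)):
            return 1e12
        x = np.zeros(3)
        x[free] = x_free
        pen = np.sum((x[penalized] / omega[penalized]) ** 2)
        return float(np.sum(((obs_c - pred) / sd) ** 2) + pen)

    n_free = int(free.sum())
    starts = [np.zeros(n_free)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        starts += [rng.normal(0.0, 0.5, size=n_free) for _ in range(n_restarts)]

    best = None
    for x0 in starts:
        if n_free == 0:
            break
        res = optimize.minimize(
            objective,
            x0=x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res

    if n_free == 0:
        params = tv
        obj, converged = objective(np.zeros(0)), True
    elif best is None or not np.isfinite(best.fun):
        raise NonConvergenceError("MAP optimization failed from every start")
    else:
        params = unpack(best.x)
        obj = float(best.fun)
        converged = bool(best.success)
        if not converged:
            logger.warning("MAP fit flagged non-converged: %s", best.message)

    auc = math.nan
    if regimen is not None:
        auc = regimen.daily_dose / params.cl
    return FitResult(
        params=params,
        objective=obj,
        converged=converged,
        auc_24=auc,
        cl_estimate=params.cl,
        n_obs=len(observations),
    )
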