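"""ER protein turnover kinetics and drug-stimulated degradation.

The receptor pool is modeled as a zero-order-synthesis / first-order-loss
turnover system in which free drug stimulates the loss rate through an
Emax term (a stimulation-of-loss indirect-response model):

    dE/dt = ksyn - kout * (1 + smax * Cu(t) / (sc50 + Cu(t))) * E,
    ksyn = kout * e0,  E(0) = e0.

E is the ER level as a fraction of the matched untreated baseline
(e0 = 1 after normalization), Cu the free plasma drug concentration in
nmol/L.  Under constant exposure the steady state is

    E_ss = e0 / (1 + smax * Cu / (sc50 + Cu)),

so the fraction of ER suppressed is 1 - 1/(1 + smax*Cu/(sc50+Cu)),
bounded by smax/(1+smax), and the instantaneous half-life shortens from
ln2/kout (basal) to ln2/(kout*(1+smax*Cu/(sc50+Cu))) under drug.

This module provides the forward simulation, closed-form suppression,
half-life estimation from decay time courses, the PK/PD fit that
estimates the in vivo degradation potency (sc50) from multi-dose ER
data, and the average suppression over a steady-state dosing interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .pk_exposure import DoseRegimen, PKParams, free_concentration_function

__all__ = [
    "ERTurnoverParams",
    "ERTimeCourse",
    "DegradationQuant",
    "HalfLifeFit",
    "ERPKPDFit",
    "simulate_er",
    "steady_state_suppression",
    "estimate_half_life",
    "fit_er_pkpd",
    "average_suppression",
    "read_er_table",
    "write_er_table",
]

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10
# dosing is considered at steady state after this many elimination half-lives
_STEADY_STATE_HALF_LIVES = 10.0


@dataclass(frozen=True)
class ERTurnoverParams:
    """Turnover parameters for the ER pool.

    kout : basal first-order degradation rate (1/h); basal half-life
        is ln2/kout.
    smax : maximal fold-stimulation of degradation (unitless); the
        maximal attainable suppression is smax/(1+smax).
    sc50 : free drug concentration (nmol/L) giving half-maximal
        stimulation of degradation — the in vivo degradation IC50.
    e0 : baseline ER level; 1 after normalization to untreated control.
    """

    kout: float
    smax: float
    sc50: float
    e0: float = 1.0

    def __post_init__(self) -> None:
        if self.kout <= 0:
            raise ValueError(f"kout must be > 0 /h, got {self.kout}")
        if self.smax < 0:
            raise ValueError(f"smax must be >= 0, got {self.smax}")
        if self.sc50 <= 0:
            raise ValueError(f"sc50 must be > 0 nmol/L, got {self.sc50}")
        if self.e0 <= 0:
            raise ValueError(f"e0 must be > 0, got {self.e0}")

    @property
    def ksyn(self) -> float:
        """Implied zero-order synthesis rate (fraction of baseline per hour)."""
        return self.kout * self.e0

    @property
    def basal_half_life_h(self) -> float:
        return np.log(2) / self.kout

    def stimulation(self, cu) -> np.ndarray | float:
        """Fold-increase factor 1 + smax*Cu/(sc50+Cu) applied to kout."""
        cu = np.asarray(cu, dtype=float)
        return 1.0 + self.smax * cu / (self.sc50 + cu)


@dataclass
class ERTimeCourse:
    """Relative ER level (fraction of baseline) over time."""

    times: np.ndarray  # hours
    level: np.ndarray  # fraction of baseline
    label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        if self.times.shape != self.level.shape:
            raise ValueError("times and level must have the same shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.label or "NA", "time_h": self.times, "rel_ER": self.level}
        )


@dataclass
class DegradationQuant:
    """Endpoint ER quantification relative to untreated control (= 1).

    ``rescale_to_anchor`` re-expresses degradation on a scale where a
    reference degrader (fulvestrant) defines 1.0; a reporting transform
    only, never used in fitting.
    """

    treatment: str
    relative_level: float
    anchor_level: float | None = None

    def rescale_to_anchor(self) -> float:
        if self.anchor_level is None:
            raise ValueError("no anchor level provided")
        anchor_deg = 1.0 - self.anchor_level
        if anchor_deg <= 0:
            raise ValueError("anchor shows no degradation; rescaling undefined")
        return (1.0 - self.relative_level) / anchor_deg


def simulate_er(
    params: ERTurnoverParams,
    free_conc_fn,
    times: np.ndarray,
    e_init: float | None = None,
    rtol: float = _ODE_RTOL,
) -> ERTimeCourse:
    """Integrate the turnover ODE along a free-concentration profile.

    ``free_conc_fn`` maps time (hours) to free drug concentration
    (nmol/L).  Starts at E(0) = e0 unless ``e_init`` overrides (used for
    washout/decay simulations started from a perturbed level).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0 h")
    e_start = params.e0 if e_init is None else float(e_init)
    ksyn, kout, smax, sc50 = params.ksyn, params.kout, params.smax, params.sc50

    def rhs(t, y):
        cu = free_conc_fn(t)
        if not isinstance(cu, float):
            cu = float(np.atleast_1d(cu)[0])
        if cu < 0:
            cu = 0.0
        return [ksyn - kout * (1.0 + smax * cu / (sc50 + cu)) * y[0]]

    t_end = float(times.max()) if times.size else 0.0
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        [e_start],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=_ODE_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ER turnover ODE integration failed: {sol.message}")
    return ERTimeCourse(times=times, level=sol.y[0])


def steady_state_suppression(params: ERTurnoverParams, free_conc) -> np.ndarray | float:
    """Fraction of ER suppressed at steady state under constant free drug.

    1 - 1/(1 + smax*Cu/(sc50+Cu)); 0 at Cu=0, saturating at
    smax/(1+smax), monotone nondecreasing in Cu.
    """
    cu = np.asarray(free_conc, dtype=float)
    if np.any(cu < 0):
        raise ValueError("free_conc must be >= 0")
    out = 1.0 - 1.0 / params.stimulation(cu)
    return out if out.ndim else float(out)


@dataclass
class HalfLifeFit:
    """Half-life from log-linear regression over the declining phase."""

    half_life_h: float
    slope_per_h: float  # d ln(level) / dt, negative
    r_squared: float
    n_points: int


def estimate_half_life(course: ERTimeCourse) -> HalfLifeFit:
    """Estimate a decay half-life as ln2/|slope| of ln(level) on time.

    Uses all points from the global maximum onward (the declining phase);
    requires >= 3 such points with positive levels and a net decline.
    """
    t = np.asarray(course.times, dtype=float)
    y = np.asarray(course.level, dtype=float)
    if np.any(y <= 0):
        raise ValueError("levels must be positive for log-linear half-life fitting")
    start = int(np.argmax(y))
    t, y = t[start:], y[start:]
    if t.size < 3:
        raise ValueError(
            "estimate_half_life requires >= 3 timepoints in the declining phase"
        )
    if y[-1] >= y[0]:
        raise ValueError("no measurable decay: series does not decline")
    res = stats.linregress(t, np.log(y))
    if res.slope >= 0:
        raise ValueError("no measurable decay: fitted slope is non-negative")
    return HalfLifeFit(
        half_life_h=float(np.log(2) / abs(res.slope)),
        slope_per_h=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


@dataclass
class ERPKPDFit:
    """Fitted turnover parameters with uncertainty and convergence info."""

    params: ERTurnoverParams
    stderr: dict[str, float | None]
    converged: bool
    residual_sd: float
    n_points: int
    message: str = ""


def fit_er_pkpd(
    er_courses: list[tuple[ERTimeCourse, DoseRegimen]],
    pk: PKParams,
    kout_init: float = 0.2,
    smax_init: float = 5.0,
    sc50_init: float = 1.0,
    ode_rtol: float = 1e-6,
) -> ERPKPDFit:
    """Fit (kout, smax, sc50) to ER time courses across dose levels.

    Each course is paired with the dosing regimen that produced it; free
    exposure is predicted from the shared PK parameters.  e0 is fixed to
    1 by normalization.  sc50 is unidentifiable from a single non-vehicle
    dose level, so >= 2 distinct positive dose levels are required.
    """
    dose_levels = {reg.dose for _, reg in er_courses if reg.dose > 0}
    if len(dose_levels) < 2:
        raise ValueError(
            "sc50 is unidentifiable: need ER courses at >= 2 distinct "
            f"positive dose levels, got {sorted(dose_levels)}"
        )

    # replicate courses under one regimen share a single predicted curve:
    # solve the ODE once per distinct regimen per residual evaluation
    groups: dict[tuple, dict] = {}
    for course, reg in er_courses:
        key = (reg.dose, reg.interval_h, reg.n_doses, reg.molecular_weight)
        g = groups.setdefault(
            key, {"cu_fn": free_concentration_function(pk, reg), "courses": []}
        )
        g["courses"].append(course)
    for g in groups.values():
        times = np.unique(np.concatenate([c.times for c in g["courses"]]))
        g["times"] = times
        g["index"] = [np.searchsorted(times, c.times) for c in g["courses"]]

    p = lmfit.Parameters()
    p.add("log_kout", value=np.log(kout_init), min=np.log(1e-3), max=np.log(10.0))
    p.add("log_smax", value=np.log(smax_init), min=np.log(1e-2), max=np.log(1e3))
    p.add("log_sc50", value=np.log(sc50_init), min=np.log(1e-4), max=np.log(1e4))

    def residual(pars):
        trial = ERTurnoverParams(
            kout=np.exp(pars["log_kout"].value),
            smax=np.exp(pars["log_smax"].value),
            sc50=np.exp(pars["log_sc50"].value),
            e0=1.0,
        )
        res = []
        for g in groups.values():
            pred = simulate_er(trial, g["cu_fn"], g["times"], rtol=ode_rtol).level
            for course, idx in zip(g["courses"], g["index"]):
                res.append(pred[idx] - course.level)
        return np.concatenate(res)

    result = lmfit.minimize(residual, p, method="leastsq")
    fitted = ERTurnoverParams(
        kout=float(np.exp(result.params["log_kout"].value)),
        smax=float(np.exp(result.params["log_smax"].value)),
        sc50=float(np.exp(result.params["log_sc50"].value)),
        e0=1.0,
    )
    # delta-method SEs on the natural scale from the log-scale covariance
    stderr: dict[str, float | None] = {}
    for name, value in (
        ("kout", fitted.kout),
        ("smax", fitted.smax),
        ("sc50", fitted.sc50),
    ):
        se_log = result.params[f"log_{name}"].stderr
        stderr[name] = float(value * se_log) if se_log is not None else None
    resid = residual(result.params)
    return ERPKPDFit(
        params=fitted,
        stderr=stderr,
        converged=bool(result.success),
        residual_sd=float(np.std(resid)),
        n_points=int(resid.size),
        message=str(result.message),
    )


def average_suppression(
    params: ERTurnoverParams, pk: PKParams, regimen: DoseRegimen
) -> float:
    """Mean fraction of ER degraded over one steady-state dosing interval.

    Dosing is run out to at least 10 elimination half-lives so the
    profile is periodic; the time-average of 1 - E(t)/e0 over the final
    interval is computed by augmenting the ODE with a cumulative-
    suppression state (quadrature at the integrator's tolerance).
    """
    if regimen.is_vehicle:
        return 0.0
    t_ss = _STEADY_STATE_HALF_LIVES * pk.elimination_half_life_h
    n_doses = max(int(np.ceil(t_ss / regimen.interval_h)) + 1, regimen.n_doses, 2)
    reg = DoseRegimen(
        dose=regimen.dose,
        interval_h=regimen.interval_h,
        n_doses=n_doses,
        molecular_weight=regimen.molecular_weight,
    )
    cu_fn = free_concentration_function(pk, reg)
    t0 = (n_doses - 1) * reg.interval_h
    t1 = n_doses * reg.interval_h

    # phase 1: run the receptor pool out to the start of the final interval
    run_in = simulate_er(params, cu_fn, np.array([0.0, t0]))
    e_at_t0 = float(run_in.level[-1])

    # phase 2: integrate [E, cumulative (1 - E/e0)] across the final interval
    def rhs(t, y):
        cu = float(np.atleast_1d(cu_fn(t))[0])
        dE = params.ksyn - params.kout * (1.0 + params.smax * cu / (params.sc50 + cu)) * y[0]
        return [dE, 1.0 - y[0] / params.e0]

    sol = solve_ivp(
        rhs,
        (t0, t1),
        [e_at_t0, 0.0],
        method="LSODA",
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
        max_step=reg.interval_h / 4,  # keep absorption transients resolved
    )
    if not sol.success:
        raise RuntimeError(f"average_suppression integration failed: {sol.message}")
    return float(sol.y[1, -1] / (t1 - t0))


def read_er_table(path) -> list[ERTimeCourse]:
    """Read a delimited ER table (sample, time_h, rel_ER) into time courses."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_h", "rel_ER"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ER table missing columns: {sorted(missing)}")
    out = []
    for label, sub in df.groupby("sample", sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            ERTimeCourse(
                times=sub["time_h"].to_numpy(dtype=float),
                level=sub["rel_ER"].to_numpy(dtype=float),
                label=str(label),
            )
        )
    return out


def write_er_table(courses: list[ERTimeCourse], path) -> None:
    pd.concat([c.to_frame() for c in courses], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
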