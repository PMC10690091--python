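"""Plasma exposure under oral dosing.

One-compartment disposition with first-order absorption and linear
kinetics; repeat-dose profiles are built by superposition of shifted
single-dose profiles.  Concentrations are carried in nmol/L throughout
(dose in mg/kg is converted via the compound's molecular weight), times
in hours, so that exposure plugs directly into the ER-turnover model
whose potency parameter is on the nmol/L free-drug scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DoseRegimen",
    "PKParams",
    "ConcentrationSeries",
    "PKFitResult",
    "predict_concentration",
    "free_concentration",
    "free_concentration_function",
    "fit_pk",
    "read_concentration_table",
    "write_concentration_table",
]

# ka == ke within this relative tolerance is handled by the analytic limit
_KA_KE_TIE_RTOL = 1e-9
_RATE_BOUNDS = (1e-3, 100.0)  # 1/h, for fitting


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing schedule.

    Parameters
    ----------
    dose : float
        Dose in mg per kg body weight; 0 encodes a vehicle arm.
    interval_h : float
        Dosing interval in hours (24 for once daily, QD).
    n_doses : int
        Number of administered doses (>= 1).
    molecular_weight : float
        Compound molecular weight in g/mol, used to convert the dose to
        nmol per kg so concentrations come out in nmol/L.
    """

    dose: float
    interval_h: float = 24.0
    n_doses: int = 1
    molecular_weight: float = 450.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0 mg/kg, got {self.dose}")
        if self.interval_h <= 0:
            raise ValueError(f"interval_h must be > 0, got {self.interval_h}")
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.molecular_weight <= 0:
            raise ValueError(
                f"molecular_weight must be > 0 g/mol, got {self.molecular_weight}"
            )

    @property
    def is_vehicle(self) -> bool:
        return self.dose == 0

    def dose_nmol_per_kg(self) -> float:
        """Administered dose in nmol/kg (mg/kg divided by g/mol is mmol/kg)."""
        return self.dose / self.molecular_weight * 1e6


@dataclass(frozen=True)
class PKParams:
    """One-compartment oral PK parameters.

    ka and ke are first-order absorption and elimination rate constants
    (1/h); ``vd_over_f`` is the apparent volume of distribution V/F in
    L/kg; ``fu`` is the unbound (free) fraction in plasma.
    """

    ka: float
    ke: float
    vd_over_f: float
    fu: float = 1.0

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError(f"ka must be > 0 /h, got {self.ka}")
        if self.ke <= 0:
            raise ValueError(f"ke must be > 0 /h, got {self.ke}")
        if self.vd_over_f <= 0:
            raise ValueError(f"vd_over_f must be > 0 L/kg, got {self.vd_over_f}")
        if not 0 < self.fu <= 1:
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")

    @property
    def elimination_half_life_h(self) -> float:
        return np.log(2) / self.ke


@dataclass
class ConcentrationSeries:
    """Total and free plasma concentration sampled over time."""

    times: np.ndarray  # hours
    total_conc: np.ndarray  # nmol/L
    free_conc: np.ndarray  # nmol/L
    animal: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.total_conc = np.asarray(self.total_conc, dtype=float)
        self.free_conc = np.asarray(self.free_conc, dtype=float)
        if self.times.shape != self.total_conc.shape:
            raise ValueError("times and total_conc must have the same shape")
        if np.any(self.total_conc < 0) or np.any(self.free_conc < 0):
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal or "NA",
                "time_h": self.times,
                "conc_nM": self.total_conc,
                "free_conc_nM": self.free_conc,
            }
        )


def _single_dose_profile(
    tau: np.ndarray, ka: float, ke: float, c_scale: float
) -> np.ndarray:
    """Concentration after one oral dose at elapsed time tau >= 0.

    c_scale = Dose / (V/F) in nmol/L.  Uses the Bateman function, with the
    ka -> ke analytic limit c_scale * ka * tau * exp(-ka*tau) at a tie.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau >= 0
    t = tau[pos]
    if np.isclose(ka, ke, rtol=_KA_KE_TIE_RTOL, atol=0.0):
        k = 0.5 * (ka + ke)
        out[pos] = c_scale * k * t * np.exp(-k * t)
    else:
        out[pos] = (
            c_scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    # guard tiny negative values from cancellation
    return np.maximum(out, 0.0)


def predict_concentration(
    params: PKParams, regimen: DoseRegimen, times: np.ndarray
) -> ConcentrationSeries:
    """Predict total and free concentration under a dosing regimen.

    Linear kinetics: the repeat-dose profile is the superposition of one
    single-dose profile per administered dose, each shifted to its dosing
    time ``i * interval_h``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0 h")
    c_scale = regimen.dose_nmol_per_kg() / params.vd_over_f
    total = np.zeros_like(times)
    for i in range(regimen.n_doses):
        total += _single_dose_profile(
            times - i * regimen.interval_h, params.ka, params.ke, c_scale
        )
    return ConcentrationSeries(
        times=times, total_conc=total, free_conc=params.fu * total
    )


def free_concentration(total: np.ndarray | float, fu: float) -> np.ndarray | float:
    """Free (unbound) concentration Cu = fu * C."""
    if not 0 < fu <= 1:
        raise ValueError(f"fu must be in (0, 1], got {fu}")
    return np.asarray(total, dtype=float) * fu if np.ndim(total) else float(total) * fu


def free_concentration_function(params: PKParams, regimen: DoseRegimen):
    """Return a callable t (hours) -> free concentration (nmol/L).

    Scalar calls (the ODE right-hand side's access pattern) take a fast
    path vectorized over doses rather than over time.
    """
    c_scale = regimen.dose_nmol_per_kg() / params.vd_over_f
    ka, ke, fu = params.ka, params.ke, params.fu
    dose_times = np.arange(regimen.n_doses) * regimen.interval_h
    tie = np.isclose(ka, ke, rtol=_KA_KE_TIE_RTOL, atol=0.0)
    k_tie = 0.5 * (ka + ke)

    def cu(t):
        t_arr = np.asarray(t, dtype=float)
        if t_arr.ndim == 0:
            tau = float(t_arr) - dose_times
            tau = tau[tau >= 0]
            if tau.size == 0:
                return 0.0
            if tie:
                total = c_scale * k_tie * np.sum(tau * np.exp(-k_tie * tau))
            else:
                total = (
                    c_scale
                    * ka
                    / (ka - ke)
                    * np.sum(np.exp(-ke * tau) - np.exp(-ka * tau))
                )
            return fu * max(total, 0.0)
        total = np.zeros_like(t_arr)
        for t0 in dose_times:
            total += _single_dose_profile(t_arr - t0, ka, ke, c_scale)
        return fu * total

    return cu


@dataclass
class PKFitResult:
    """Outcome of fitting the one-compartment model to observed concentrations."""

    params: PKParams
    converged: bool
    residual_sd_log: float
    n_points: int
    message: str = ""


def fit_pk(
    series: ConcentrationSeries,
    regimen: DoseRegimen,
    fu: float = 1.0,
) -> PKFitResult:
    """Least-squares fit of (ka, ke, V/F) on the log-concentration scale.

    Log-scale residuals stabilize the fit over the profile's wide dynamic
    range.  Requires >= 4 distinct timepoints with drug signal; the free
    fraction is not identifiable from total concentration and is passed
    through.
    """
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.total_conc, dtype=float)
    keep = c > 0
    if len(np.unique(t)) < 4:
        raise ValueError("fit_pk requires >= 4 distinct timepoints")
    if not np.any(keep):
        raise ValueError("no drug signal: all observed concentrations are zero")
    t, c = t[keep], c[keep]

    lo, hi = _RATE_BOUNDS
    p = lmfit.Parameters()
    p.add("log_ka", value=0.0, min=np.log(lo), max=np.log(hi))
    p.add("log_ke", value=np.log(0.1), min=np.log(lo), max=np.log(hi))
    p.add("log_vdf", value=np.log(1.0), min=np.log(1e-3), max=np.log(1e3))

    def residual(pars):
        pk = PKParams(
            ka=np.exp(pars["log_ka"].value),
            ke=np.exp(pars["log_ke"].value),
            vd_over_f=np.exp(pars["log_vdf"].value),
            fu=fu,
        )
        pred = predict_concentration(pk, regimen, t).total_conc
        return np.log(np.maximum(pred, 1e-12)) - np.log(c)

    result = lmfit.minimize(residual, p, method="leastsq")
    fitted = PKParams(
        ka=float(np.exp(result.params["log_ka"].value)),
        ke=float(np.exp(result.params["log_ke"].value)),
        vd_over_f=float(np.exp(result.params["log_vdf"].value)),
        fu=fu,
    )
    resid = residual(result.params)
    return PKFitResult(
        params=fitted,
        converged=bool(result.success),
        residual_sd_log=float(np.std(resid)),
        n_points=int(t.size),
        message=str(result.message),
    )


def read_concentration_table(path, fu: float = 1.0) -> dict[str, ConcentrationSeries]:
    """Read a delimited table (animal, time_h, conc_nM) into series per animal."""
    df = pd.read_csv(path, sep="\t")
    required = {"animal", "time_h", "conc_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")
    out = {}
    for animal, sub in df.groupby("animal", sort=True):
        sub = sub.sort_values("time_h")
        total = sub["conc_nM"].to_numpy(dtype=float)
        free = (
            sub["free_conc_nM"].to_numpy(dtype=float)
            if "free_conc_nM" in sub.columns
            else fu * total
        )
        out[str(animal)] = ConcentrationSeries(
            times=sub["time_h"].to_numpy(dtype=float),
            total_conc=total,
            free_conc=free,
            animal=str(animal),
        )
    return out


def write_concentration_table(series: list[ConcentrationSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
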