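"""Tumor growth simulation and xenograft efficacy analytics.

Growth follows the per-animal exponential model

    log10 V(t) = a + b * t + error

used for growth-rate summaries, with volumes below 15 mm^3 floored to
15 mm^3 before the log transform.  Treatment acts through the ER level:
the instantaneous log-growth slope is b0 - bkill * (1 - E(t)/e0)^gamma,
which reduces exactly to the exponential model at vehicle (E = e0).

Efficacy statistics:
  * %TV change = (V_end - V_baseline) / V_baseline * 100 per animal;
  * TGI from geometric-mean fold changes: with GM_g the geometric mean
    over animals of V_end/V_baseline, TGI% = 100 * (1 - (GM_T - 1)/(GM_C - 1)),
    so an identical arm scores 0% and a static arm 100%, values > 100%
    indicating regression (reported unclipped);
  * one-tailed unequal-variance (Welch) t test on log(V_end/V_baseline),
    alternative "treated grows less than control".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .er_turnover import ERTimeCourse

__all__ = [
    "VOLUME_FLOOR_MM3",
    "TumorVolumeSeries",
    "TumorGrowthParams",
    "GrowthRateFit",
    "TGIResult",
    "simulate_tumor",
    "fit_growth_rate",
    "percent_tv_change",
    "log_fold_changes",
    "tgi",
    "compare_to_vehicle",
    "read_volume_table",
    "write_volume_table",
]

VOLUME_FLOOR_MM3 = 15.0


@dataclass
class TumorVolumeSeries:
    """Caliper tumor volumes (mm^3) for one animal over study days."""

    animal: str
    arm: str
    days: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.days.shape != self.volume.shape:
            raise ValueError("days and volume must have the same shape")
        if np.any(np.diff(self.days) < 0):
            raise ValueError("days must be non-decreasing")
        if np.any(self.volume <= 0):
            raise ValueError("volumes must be positive")

    @property
    def baseline(self) -> float:
        return float(self.volume[0])

    @property
    def final(self) -> float:
        return float(self.volume[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "arm": self.arm,
                "day": self.days,
                "volume_mm3": self.volume,
            }
        )


@dataclass(frozen=True)
class TumorGrowthParams:
    """Parameters linking ER suppression to tumor growth.

    b0 : intrinsic growth rate, log10(mm^3) per day (vehicle slope).
    bkill : maximal extra regression rate attributable to complete ER
        loss, log10(mm^3) per day.
    gamma : shape of the ER -> growth link; 1 is linear in suppression.
    """

    b0: float
    bkill: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.bkill < 0:
            raise ValueError(f"bkill must be >= 0, got {self.bkill}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def simulate_tumor(
    params: TumorGrowthParams,
    er_course: ERTimeCourse,
    days: np.ndarray,
    v0: float,
    e0: float = 1.0,
) -> TumorVolumeSeries:
    """Deterministic tumor trajectory driven by an ER time course.

    d log10 V / dt = b0 - bkill * (1 - E(t)/e0)^gamma, integrated by
    trapezoid on a fine daily grid; E(t) is linearly interpolated from
    the ER course (times in hours) and held at its last value beyond
    the course's coverage.
    """
    days = np.asarray(days, dtype=float)
    if v0 <= 0:
        raise ValueError(f"v0 must be > 0 mm^3, got {v0}")
    if np.any(days < 0):
        raise ValueError("study days must be >= 0")
    t_end = float(days.max()) if days.size else 0.0
    # fine grid (0.05 d) keeps the trapezoid error far below biological noise
    grid = np.union1d(np.arange(0.0, t_end + 0.05, 0.05), days)
    er = np.interp(
        grid * 24.0,
        er_course.times,
        er_course.level,
        left=er_course.level[0],
        right=er_course.level[-1],
    )
    suppression = np.clip(1.0 - er / e0, 0.0, None)
    slope = params.b0 - params.bkill * suppression**params.gamma
    log10_v = np.log10(v0) + _cumtrapz(slope, grid)
    volume = 10.0 ** np.interp(days, grid, log10_v)
    return TumorVolumeSeries(animal="sim", arm="sim", days=days, volume=volume)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


@dataclass
class GrowthRateFit:
    """Exponential-model fit log10 V = a + b*day on floored volumes."""

    a: float  # log10 mm^3 intercept
    b: float  # log10 mm^3 / day slope
    residual_sd: float
    n_points: int


def fit_growth_rate(series: TumorVolumeSeries) -> GrowthRateFit:
    """OLS of log10(max(V, 15 mm^3)) on study day."""
    if series.days.size < 3:
        raise ValueError("fit_growth_rate requires >= 3 measurement days")
    floored = np.maximum(series.volume, VOLUME_FLOOR_MM3)
    y = np.log10(floored)
    res = stats.linregress(series.days, y)
    resid = y - (res.intercept + res.slope * series.days)
    return GrowthRateFit(
        a=float(res.intercept),
        b=float(res.slope),
        residual_sd=float(np.std(resid, ddof=2)) if series.days.size > 2 else 0.0,
        n_points=int(series.days.size),
    )


def percent_tv_change(series: TumorVolumeSeries) -> float:
    """(V_end - V_baseline) / V_baseline * 100."""
    if series.baseline <= 0:
        raise ValueError("baseline volume must be > 0")
    return (series.final - series.baseline) / series.baseline * 100.0


def log_fold_changes(arm: list[TumorVolumeSeries]) -> np.ndarray:
    """Natural log of V_end/V_baseline per animal (the Welch-test variable)."""
    return np.array([np.log(s.final / s.baseline) for s in arm])


@dataclass
class TGIResult:
    """Arm-level tumor growth inhibition vs a control arm."""

    tv_change_pct: np.ndarray  # per treated animal
    gm_treated: float  # geometric mean V_end/V_baseline, treated
    gm_control: float
    tgi_pct: float | None  # None when undefined (non-growing control)
    p_value: float | None
    defined: bool
    note: str = ""


def _geometric_mean_fold_change(arm: list[TumorVolumeSeries]) -> float:
    return float(np.exp(np.mean(log_fold_changes(arm))))


def tgi(
    treated: list[TumorVolumeSeries],
    control: list[TumorVolumeSeries],
    with_p: bool = True,
) -> TGIResult:
    """Tumor growth inhibition from geometric-mean fold changes.

    TGI% = 100 * (1 - (GM_T - 1)/(GM_C - 1)) requires a net-growing
    control (GM_C > 1); otherwise the result is flagged undefined.
    Stasis in the treated arm (GM_T = 1) gives exactly 100%; regression
    exceeds 100% and is reported unclipped.
    """
    if not treated or not control:
        raise ValueError("both treated and control arms must be non-empty")
    gm_t = _geometric_mean_fold_change(treated)
    gm_c = _geometric_mean_fold_change(control)
    p = None
    if with_p and len(treated) >= 2 and len(control) >= 2:
        p = compare_to_vehicle(treated, control)
    changes = np.array([percent_tv_change(s) for s in treated])
    if gm_c <= 1.0:
        return TGIResult(
            tv_change_pct=changes,
            gm_treated=gm_t,
            gm_control=gm_c,
            tgi_pct=None,
            p_value=p,
            defined=False,
            note=f"control arm did not grow (GM fold change {gm_c:.3f} <= 1); TGI undefined",
        )
    value = 100.0 * (1.0 - (gm_t - 1.0) / (gm_c - 1.0))
    return TGIResult(
        tv_change_pct=changes,
        gm_treated=gm_t,
        gm_control=gm_c,
        tgi_pct=float(value),
        p_value=p,
        defined=True,
    )


def compare_to_vehicle(
    treated: list[TumorVolumeSeries],
    control: list[TumorVolumeSeries],
    two_tailed: bool = False,
) -> float:
    """Welch t test on log(V_end/V_baseline), one-tailed by default.

    The one-tailed alternative is "treated grows less than control",
    matching the efficacy question; a two-tailed p is available behind
    the flag.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("compare_to_vehicle requires >= 2 animals per arm")
    x_t = log_fold_changes(treated)
    x_c = log_fold_changes(control)
    alternative = "two-sided" if two_tailed else "less"
    res = stats.ttest_ind(x_t, x_c, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def align_arms_to_common_end(
    treated: list[TumorVolumeSeries],
    control: list[TumorVolumeSeries],
    locf_window_days: float = 7.0,
) -> tuple[list[TumorVolumeSeries], list[TumorVolumeSeries], list[str]]:
    """Truncate both arms to the last day both have measurements.

    Animals whose last measurement falls short of that day carry their
    last observation forward if within ``locf_window_days``; otherwise
    they are excluded.  Returns the aligned arms plus log lines naming
    every animal that was carried forward or dropped.
    """
    if not treated or not control:
        raise ValueError("both arms must be non-empty")
    end_day = min(
        max(s.days.max() for s in treated), max(s.days.max() for s in control)
    )
    log: list[str] = []

    def align(arm: list[TumorVolumeSeries]) -> list[TumorVolumeSeries]:
        out = []
        for s in arm:
            keep = s.days <= end_day
            days, vol = s.days[keep], s.volume[keep]
            last = days.max()
            if last < end_day:
                if end_day - last <= locf_window_days:
                    days = np.append(days, end_day)
                    vol = np.append(vol, vol[-1])
                    log.append(
                        f"{s.animal} ({s.arm}): last observation day {last:g} "
                        f"carried forward to day {end_day:g}"
                    )
                else:
                    log.append(
                        f"{s.animal} ({s.arm}): excluded, last observation day "
                        f"{last:g} more than {locf_window_days:g} d before day {end_day:g}"
                    )
                    continue
            out.append(
                TumorVolumeSeries(animal=s.animal, arm=s.arm, days=days, volume=vol)
            )
        return out

    return align(treated), align(control), log


def read_volume_table(path) -> list[TumorVolumeSeries]:
    """Read a delimited volume table (animal, arm, day, volume_mm3)."""
    df = pd.read_csv(path, sep="\t")
    required = {"animal", "arm", "day", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"volume table missing columns: {sorted(missing)}")
    out = []
    for (animal, arm), sub in df.groupby(["animal", "arm"], sort=True):
        sub = sub.sort_values("day")
        out.append(
            TumorVolumeSeries(
                animal=str(animal),
                arm=str(arm),
                days=sub["day"].to_numpy(dtype=float),
                volume=sub["volume_mm3"].to_numpy(dtype=float),
            )
        )
    return out


def write_volume_table(series: list[TumorVolumeSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
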