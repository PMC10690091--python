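"""Proliferation-assay normalization and 4PL concentration-response fitting.

Live counts (total minus dead) are normalized so that the day-0 plate
mean defines 0% growth and the untreated end-of-assay mean defines 100%:

    response = (treated - day0) / (untreated_end - day0).

Negative responses mean net cell loss (cytotoxicity) and are retained.
The normalized ladder is fit with a four-parameter logistic on
log10-concentration; the midpoint of the fitted curve is the (relative)
IC50, reported alongside pIC50 = -log10(IC50 in mol/L) and the fitted
bottom-of-curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "PlateCounts",
    "FourPLFit",
    "normalize_growth",
    "fit_4pl",
    "four_pl",
    "bottom_of_curve",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "read_plate_table",
]

# a response range below this is treated as flat (no fittable curve)
_FLAT_RESPONSE_RANGE = 0.1
_UNIT_TO_MOLAR = {"M": 1.0, "mol/L": 1.0, "mmol/L": 1e-3, "umol/L": 1e-6, "nmol/L": 1e-9}


@dataclass
class PlateCounts:
    """Live-cell counts for one compound on one plate.

    day0_mean : mean live count of the untreated day-0 plate (0% growth).
    untreated_end_mean : mean live count of the untreated wells at the
        assay endpoint, day 7 by default or day 6 for lines configured
        with ``endpoint_day`` (100% growth).
    conc : per-well drug concentration in mol/L.
    treated : per-well live count at the endpoint.
    """

    day0_mean: float
    untreated_end_mean: float
    conc: np.ndarray
    treated: np.ndarray
    endpoint_day: int = 7

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.treated = np.asarray(self.treated, dtype=float)
        if self.conc.shape != self.treated.shape:
            raise ValueError("conc and treated must have the same shape")
        if self.day0_mean < 0 or self.untreated_end_mean < 0 or np.any(self.treated < 0):
            raise ValueError("cell counts must be >= 0")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be > 0 mol/L")


def normalize_growth(plate: PlateCounts) -> tuple[np.ndarray, np.ndarray]:
    """Normalized growth per well: 0 = day-0 count, 1 = untreated endpoint.

    Returns (conc in mol/L, response).  Responses below 0 (counts under
    the day-0 plate, i.e. net cell kill) are retained.
    """
    window = plate.untreated_end_mean - plate.day0_mean
    if window <= 0:
        raise ValueError(
            "no growth window: untreated endpoint count "
            f"({plate.untreated_end_mean:g}) does not exceed day-0 count "
            f"({plate.day0_mean:g})"
        )
    response = (plate.treated - plate.day0_mean) / window
    return plate.conc.copy(), response


def four_pl(conc: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic response at concentration (mol/L)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def pic50_from_ic50(ic50_molar: float) -> float:
    if ic50_molar <= 0:
        raise ValueError("ic50 must be > 0 mol/L")
    return float(-np.log10(ic50_molar))


def ic50_from_pic50(pic50: float) -> float:
    return float(10.0 ** (-pic50))


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ic50: float  # mol/L
    hill: float
    pic50: float
    converged: bool
    in_range: bool  # IC50 inside the tested concentration range
    degenerate: bool = False
    residual_sd: float = 0.0
    message: str = ""


def fit_4pl(conc: np.ndarray, response: np.ndarray) -> FourPLFit:
    """Least-squares 4PL fit on log10 concentration.

    Requires >= 6 concentrations spanning >= 2 logs.  A flat response
    (range < 0.1 normalized units) returns a degenerate flag instead of
    a meaningless IC50.  Initialization: top/bottom from the data
    extremes, IC50 at the tested concentration nearest half-range,
    hill = 1.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    uniq = np.unique(conc)
    if uniq.size < 6:
        raise ValueError("fit_4pl requires >= 6 distinct concentrations")
    span = np.log10(uniq.max() / uniq.min())
    if span < 2.0:
        raise ValueError(
            f"concentration ladder spans {span:.2f} logs; >= 2 required"
        )
    if response.max() - response.min() < _FLAT_RESPONSE_RANGE:
        return FourPLFit(
            top=float(response.mean()),
            bottom=float(response.mean()),
            ic50=np.nan,
            hill=np.nan,
            pic50=np.nan,
            converged=False,
            in_range=False,
            degenerate=True,
            message="flat response; no concentration dependence to fit",
        )

    half = 0.5 * (response.max() + response.min())
    ic50_init = float(conc[np.argmin(np.abs(response - half))])
    p = lmfit.Parameters()
    p.add("top", value=float(response.max()))
    p.add("bottom", value=float(response.min()))
    p.add(
        "log10_ic50",
        value=np.log10(ic50_init),
        min=np.log10(uniq.min()) - 3,
        max=np.log10(uniq.max()) + 3,
    )
    p.add("hill", value=1.0, min=0.1, max=10.0)

    def residual(pars):
        return (
            four_pl(
                conc,
                pars["top"].value,
                pars["bottom"].value,
                10.0 ** pars["log10_ic50"].value,
                pars["hill"].value,
            )
            - response
        )

    result = lmfit.minimize(residual, p, method="leastsq")
    ic50 = float(10.0 ** result.params["log10_ic50"].value)
    top = float(result.params["top"].value)
    bottom = float(result.params["bottom"].value)
    if top < bottom:  # canonical orientation: top is the high-response asymptote
        top, bottom = bottom, top
    return FourPLFit(
        top=top,
        bottom=bottom,
        ic50=ic50,
        hill=float(result.params["hill"].value),
        pic50=pic50_from_ic50(ic50),
        converged=bool(result.success),
        in_range=bool(uniq.min() <= ic50 <= uniq.max()),
        residual_sd=float(np.std(residual(result.params))),
        message=str(result.message),
    )


def bottom_of_curve(fit: FourPLFit) -> tuple[float, bool]:
    """Fitted response at saturating drug; flags negative values as cytotoxic.

    A bottom numerically indistinguishable from zero (|bottom| < 1e-6)
    is not called cytotoxic.
    """
    if fit.degenerate:
        raise ValueError("degenerate fit has no bottom-of-curve")
    return fit.bottom, fit.bottom < -1e-6


def read_plate_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (well, conc, conc_unit, live_count, timepoint) into a dose ladder.

    Rows with timepoint 'day0' and 'untreated' define the normalization
    anchors; the remaining endpoint rows carry the treated ladder.
    Concentrations are converted to mol/L from the unit column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"well", "conc", "conc_unit", "live_count", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    day0 = df[df["timepoint"] == "day0"]["live_count"].mean()
    untreated = df[df["timepoint"] == "untreated"]["live_count"].mean()
    treated = df[~df["timepoint"].isin(["day0", "untreated"])]
    bad_units = set(treated["conc_unit"]) - set(_UNIT_TO_MOLAR)
    if bad_units:
        raise ValueError(f"unknown concentration units: {sorted(bad_units)}")
    conc_molar = treated["conc"].to_numpy(dtype=float) * np.array(
        [_UNIT_TO_MOLAR[u] for u in treated["conc_unit"]]
    )
    plate = PlateCounts(
        day0_mean=float(day0),
        untreated_end_mean=float(untreated),
        conc=conc_molar,
        treated=treated["live_count"].to_numpy(dtype=float),
    )
    return normalize_growth(plate)
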