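"""Synthetic preclinical studies with known ground truth.

Generates the full data bundle a SERD xenograft study produces — plasma
PK samples, ER degradation time courses, caliper tumor-volume
trajectories, and treated/control expression matrices — from explicit
ground-truth parameters, so that every downstream estimator can be
tested for recovery against the truth that generated its input.

Noise model: multiplicative lognormal on volumes, concentrations and ER
levels (caliper and bioanalytical error scale with the measurement),
additive Gaussian on log-expression.  A single integer seed drives
deterministic per-animal streams (seeded as (seed, arm index, animal
index)), so any per-arm subset of a bundle is reproducible on its own.

Default study conditions mirror a dose-ranging xenograft experiment:
enrollment at 150-300 mm^3, twice-weekly caliper measurement
(days 0, 3, 7, 10, 14, ...), once-daily oral dosing at 1/3/10/30 mg/kg
against vehicle, 8 animals per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .er_turnover import ERTimeCourse, ERTurnoverParams, simulate_er
from .pk_exposure import (
    ConcentrationSeries,
    DoseRegimen,
    PKParams,
    free_concentration_function,
    predict_concentration,
)
from .signature_scoring import ExpressionMatrix, GeneSignature
from .tumor_growth import TumorGrowthParams, TumorVolumeSeries, simulate_tumor

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "GroundTruth",
    "StudyBundle",
    "default_design",
    "default_truth",
    "simulate_study",
    "simulate_expression",
    "simulate_decay_course",
    "write_bundle",
    "twice_weekly_days",
]

# sampling schedules (hours post first dose)
DEFAULT_PK_TIMES_H = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
DEFAULT_ER_TIMES_H = np.array(
    [0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 25.0, 28.0, 32.0, 36.0, 48.0]
)


def twice_weekly_days(duration_days: float) -> list[float]:
    """Measurement days 0, 3, 7, 10, 14, ... out to the study end."""
    days, d, step = [0.0], 0.0, [3.0, 4.0]
    i = 0
    while d + step[i % 2] <= duration_days:
        d += step[i % 2]
        days.append(d)
        i += 1
    return days


@dataclass(frozen=True)
class StudyDesign:
    """Arms, group size, enrollment window and measurement schedule.

    ``arms`` maps arm label to a DoseRegimen, with None encoding the
    vehicle arm.
    """

    arms: tuple[tuple[str, DoseRegimen | None], ...]
    n_per_arm: int = 8
    enrollment_volume_range: tuple[float, float] = (150.0, 300.0)
    duration_days: float = 28.0
    measurement_days: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.arms) == 0:
            raise ValueError("arms must be non-empty")
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        lo, hi = self.enrollment_volume_range
        if not (0 < lo < hi):
            raise ValueError(
                f"enrollment_volume_range must satisfy 0 < min < max, got ({lo}, {hi})"
            )
        if self.duration_days <= 0:
            raise ValueError(f"duration_days must be > 0, got {self.duration_days}")
        days = (
            self.measurement_days
            if self.measurement_days
            else tuple(twice_weekly_days(self.duration_days))
        )
        if days[0] != 0 or np.any(np.diff(days) <= 0):
            raise ValueError(
                "measurement_days must be strictly increasing and start at 0"
            )
        object.__setattr__(self, "measurement_days", tuple(days))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes and the study seed.

    volume_cv, conc_cv, er_cv are lognormal coefficients of variation;
    expression_sd is the additive SD on log-expression.  Zero everywhere
    reproduces the deterministic models exactly.
    """

    volume_cv: float = 0.15
    conc_cv: float = 0.15
    er_cv: float = 0.15
    expression_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("volume_cv", "conc_cv", "er_cv", "expression_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-1 multiplicative noise; exactly 1 when cv == 0."""
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameters a recovery test compares against."""

    pk: PKParams
    er: ERTurnoverParams
    growth: TumorGrowthParams
    signature_shift: float = 0.0  # z-units applied to treated samples


def default_truth() -> GroundTruth:
    """Realistic SERD-like ground truth.

    PK: oral absorption ka 1/h, elimination half-life ~7 h, V/F 5 L/kg,
    1% free fraction — at 10 mg/kg QD this puts the average free
    exposure tens of nmol/L above the 0.4 nmol/L degradation sc50,
    giving deep, dose-responsive ER loss.  ER: basal half-life 3 h
    (kout = ln2/3), maximal 9-fold stimulation of loss.  Growth:
    vehicle slope 0.02 log10/day; full ER loss converts growth to
    regression.
    """
    return GroundTruth(
        pk=PKParams(ka=1.0, ke=0.1, vd_over_f=5.0, fu=0.01),
        er=ERTurnoverParams(kout=np.log(2) / 3.0, smax=9.0, sc50=0.4, e0=1.0),
        growth=TumorGrowthParams(b0=0.02, bkill=0.06, gamma=1.0),
    )


def default_design(
    doses: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0),
    n_per_arm: int = 8,
    duration_days: float = 28.0,
    molecular_weight: float = 450.0,
) -> StudyDesign:
    """Vehicle + once-daily dose-ranging arms, twice-weekly calipers."""
    n_doses = int(np.ceil(duration_days))
    arms: list[tuple[str, DoseRegimen | None]] = [("vehicle", None)]
    for d in doses:
        arms.append(
            (
                f"{d:g}mpk_qd",
                DoseRegimen(
                    dose=d,
                    interval_h=24.0,
                    n_doses=n_doses,
                    molecular_weight=molecular_weight,
                ),
            )
        )
    return StudyDesign(arms=tuple(arms), n_per_arm=n_per_arm, duration_days=duration_days)


@dataclass
class StudyBundle:
    """Everything one simulated study produced, plus the truth that made it."""

    design: StudyDesign
    truth: GroundTruth
    noise: NoiseModel
    volumes: list[TumorVolumeSeries]
    concentrations: list[ConcentrationSeries]
    er_courses: list[tuple[ERTimeCourse, str]]  # (course, arm label)
    regimens: dict[str, DoseRegimen | None]

    def volumes_by_arm(self) -> dict[str, list[TumorVolumeSeries]]:
        out: dict[str, list[TumorVolumeSeries]] = {a: [] for a, _ in self.design.arms}
        for s in self.volumes:
            out[s.arm].append(s)
        return out

    def er_by_arm(self) -> dict[str, list[ERTimeCourse]]:
        out: dict[str, list[ERTimeCourse]] = {a: [] for a, _ in self.design.arms}
        for course, arm in self.er_courses:
            out[arm].append(course)
        return out


def _animal_rng(seed: int, arm_idx: int, animal_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, arm_idx, animal_idx]))


def simulate_study(
    design: StudyDesign,
    truth: GroundTruth,
    noise: NoiseModel,
    pk_times_h: np.ndarray = DEFAULT_PK_TIMES_H,
    er_times_h: np.ndarray = DEFAULT_ER_TIMES_H,
) -> StudyBundle:
    """Simulate one complete study.

    Per arm: free exposure from the true PK, the deterministic ER course
    from the turnover ODE, and the deterministic tumor trajectory from
    the ER-driven growth model; each animal then gets its own enrollment
    volume (uniform on the enrollment range) and multiplicative
    measurement noise from its own seeded stream.
    """
    days = np.asarray(design.measurement_days, dtype=float)
    lo, hi = design.enrollment_volume_range
    volumes: list[TumorVolumeSeries] = []
    concs: list[ConcentrationSeries] = []
    ers: list[tuple[ERTimeCourse, str]] = []
    regimens: dict[str, DoseRegimen | None] = {}

    for arm_idx, (arm, regimen) in enumerate(design.arms):
        regimens[arm] = regimen
        if regimen is None:
            cu_fn = lambda t: np.zeros_like(np.atleast_1d(np.asarray(t, float)))
        else:
            cu_fn = free_concentration_function(truth.pk, regimen)

        # deterministic ER driver over the whole study (hourly grid)
        driver_times = np.arange(0.0, design.duration_days * 24.0 + 1.0, 1.0)
        er_driver = simulate_er(truth.er, cu_fn, driver_times)
        # deterministic ER course at the biomarker sampling times
        er_det = simulate_er(truth.er, cu_fn, np.asarray(er_times_h, float))

        for animal_idx in range(design.n_per_arm):
            rng = _animal_rng(noise.seed, arm_idx, animal_idx)
            animal = f"{arm}_a{animal_idx + 1}"

            v0 = lo + (hi - lo) * rng.uniform()
            traj = simulate_tumor(
                truth.growth, er_driver, days, v0, e0=truth.er.e0
            )
            vol = traj.volume * _lognormal_factors(rng, noise.volume_cv, days.size)
            vol[0] = v0  # baseline is the enrollment measurement itself
            volumes.append(
                TumorVolumeSeries(animal=animal, arm=arm, days=days, volume=vol)
            )

            if regimen is not None:
                det = predict_concentration(
                    truth.pk, regimen, np.asarray(pk_times_h, float)
                )
                total = det.total_conc * _lognormal_factors(
                    rng, noise.conc_cv, det.times.size
                )
                concs.append(
                    ConcentrationSeries(
                        times=det.times,
                        total_conc=total,
                        free_conc=truth.pk.fu * total,
                        animal=animal,
                    )
                )

            level = er_det.level * _lognormal_factors(
                rng, noise.er_cv, er_det.times.size
            )
            ers.append(
                (
                    ERTimeCourse(times=er_det.times, level=level, label=animal),
                    arm,
                )
            )

    return StudyBundle(
        design=design,
        truth=truth,
        noise=noise,
        volumes=volumes,
        concentrations=concs,
        er_courses=ers,
        regimens=regimens,
    )


def simulate_expression(
    n_genes: int,
    n_samples_per_group: int,
    signature: GeneSignature,
    shift: float,
    noise: NoiseModel,
    baseline_mean: float = 8.0,
    baseline_spread: float = 2.0,
) -> ExpressionMatrix:
    """Two-group expression matrix with a planted signature effect.

    Non-signature genes are identically distributed in both groups.
    In the treated group, induced signature genes are shifted up and
    repressed genes down by ``shift`` z-units (i.e. shift *
    expression_sd on the log-expression scale).  Samples are labeled
    'control' / 'treated'.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if n_samples_per_group < 2:
        raise ValueError(
            f"n_samples_per_group must be >= 2, got {n_samples_per_group}"
        )
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    missing = signature.genes.difference(genes)
    if len(missing):
        raise ValueError(
            f"signature genes absent from simulated matrix: {list(missing[:10])}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 917]))
    n_tot = 2 * n_samples_per_group
    mu = baseline_mean + baseline_spread * rng.standard_normal(n_genes)
    vals = mu[:, None] + noise.expression_sd * rng.standard_normal((n_genes, n_tot))
    samples = [f"ctrl_{i + 1}" for i in range(n_samples_per_group)] + [
        f"trt_{i + 1}" for i in range(n_samples_per_group)
    ]
    df = pd.DataFrame(vals, index=genes, columns=samples)
    directions = signature.directions.reindex(genes).fillna(0.0)
    df.iloc[:, n_samples_per_group:] = df.iloc[:, n_samples_per_group:].add(
        directions * shift * noise.expression_sd, axis=0
    )
    groups = pd.Series(
        ["control"] * n_samples_per_group + ["treated"] * n_samples_per_group,
        index=samples,
        name="group",
    )
    return ExpressionMatrix(values=df, groups=groups)


def simulate_decay_course(
    half_life_h: float, times_h: np.ndarray, noise: NoiseModel
) -> ERTimeCourse:
    """Exponential ER decay exp(-ln2 * t / half_life) with lognormal noise."""
    if half_life_h <= 0:
        raise ValueError(f"half_life_h must be > 0, got {half_life_h}")
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0):
        raise ValueError("times must be >= 0 h")
    level = np.exp(-np.log(2) * times_h / half_life_h)
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 431]))
    level = level * _lognormal_factors(rng, noise.er_cv, times_h.size)
    return ERTimeCourse(times=times_h, level=level, label="decay")


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_builtin(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_bundle(bundle: StudyBundle, out_dir) -> None:
    """Write the bundle as plain delimited tables plus a truth echo.

    Files: volumes.tsv (animal, arm, day, volume_mm3), conc.tsv
    (animal, time_h, conc_nM, free_conc_nM), er.tsv (sample, arm,
    time_h, rel_ER), truth.yaml (design, noise and generating
    parameters).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.concat([s.to_frame() for s in bundle.volumes], ignore_index=True).to_csv(
        out / "volumes.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if bundle.concentrations:
        pd.concat(
            [s.to_frame() for s in bundle.concentrations], ignore_index=True
        ).to_csv(out / "conc.tsv", sep="\t", index=False, float_format="%.10g")
    er_frames = []
    for course, arm in bundle.er_courses:
        f = course.to_frame()
        f.insert(1, "arm", arm)
        er_frames.append(f)
    pd.concat(er_frames, ignore_index=True).to_csv(
        out / "er.tsv", sep="\t", index=False, float_format="%.10g"
    )
    echo = {
        "design": {
            "arms": [
                {
                    "label": label,
                    "regimen": None if reg is None else asdict(reg),
                }
                for label, reg in bundle.design.arms
            ],
            "n_per_arm": bundle.design.n_per_arm,
            "enrollment_volume_range": list(bundle.design.enrollment_volume_range),
            "duration_days": bundle.design.duration_days,
            "measurement_days": list(bundle.design.measurement_days),
        },
        "noise": asdict(bundle.noise),
        "truth": {
            "pk": asdict(bundle.truth.pk),
            "er": asdict(bundle.truth.er),
            "growth": asdict(bundle.truth.growth),
            "signature_shift": bundle.truth.signature_shift,
        },
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(_to_builtin(echo), fh, sort_keys=False)
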