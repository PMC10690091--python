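# Methods

## Scope and model chain

The package links three models in series — oral PK → ER turnover →
tumor growth — and surrounds them with the estimators and summary
statistics a preclinical SERD efficacy program uses. Each stage is
usable on real tabular data; the synthetic-study generator exists so
that each estimator can be checked for recovery against known
generating parameters.

## Pharmacokinetics

One-compartment disposition with first-order absorption and linear
kinetics. A dose `D` (mg/kg) is converted to nmol/kg through the
compound's molecular weight, and the single-dose concentration is the
Bateman function

    C(t) = (D / (V/F)) · ka/(ka − ke) · (e^(−ke·t) − e^(−ka·t)),

with the analytic limit `(D/(V/F))·k·t·e^(−k·t)` when `ka = ke`
(detected at relative tolerance 1e−9). Repeat dosing is handled by
superposition; free concentration is `fu·C`. This is the simplest
structure consistent with dose-proportional exposure; multi-compartment
and saturable kinetics are out of scope. PK fitting runs on the
log-concentration scale (the profile spans orders of magnitude) with
rate constants bounded in (1e−3, 100)/h and log-parameterized so
positivity is structural.

Units are fixed throughout: hours, nmol/L, mg/kg, L/kg. The nmol/L
scale was chosen so the degradation potency is directly comparable to
sub-nanomolar free IC50s typical of this drug class.

## ER turnover

The receptor pool follows a stimulation-of-loss indirect-response
model: synthesis is zero-order (`ksyn = kout·e0`), loss first-order,
and free drug multiplies the loss rate through an Emax term,

    dE/dt = ksyn − kout·(1 + smax·Cu(t)/(sc50 + Cu(t)))·E.

Assumptions: degradation is the drug's only action on the pool
(consistent with proteasome-mediated loss), stimulation is
instantaneous in `Cu` (no effect-compartment delay), and `E` is always
analyzed as a fraction of the matched untreated baseline, so `e0 = 1`
after normalization. Useful closed forms, both used as test oracles:

* steady state under constant exposure:
  `E_ss = e0 / (1 + smax·Cu/(sc50 + Cu))`;
* suppressed fraction `1 − 1/(1 + smax·Cu/(sc50+Cu))`, bounded by
  `smax/(1+smax)`;
* half-life under constant drug `ln2/(kout·(1 + smax·Cu/(sc50+Cu)))`.

Numerics: LSODA with rtol 1e−8 / atol 1e−10 for forward simulation.
The multi-dose PK/PD fit solves the ODE at rtol 1e−6 inside the
residual (the residual is noise-dominated there) and shares one
solution across replicate animals of the same regimen. Average
suppression over a dosing interval is computed by augmenting the ODE
with a cumulative `1 − E/e0` state after a run-in of 10 elimination
half-lives, with the maximum step capped at a quarter interval so
absorption transients are resolved.

Half-life estimation is `ln2/|slope|` from ordinary least squares of
`ln(level)` on time, using all points from the global maximum onward;
at least 3 declining points and a net decline are required, otherwise
the series is rejected as having no measurable decay. Identifiability:
`sc50` cannot be separated from `smax` with a single positive dose
level, so the PK/PD fit refuses such input.

The rescaling of endpoint degradation values to a reference degrader
(anchor = 1.0) is a reporting transform only and never enters fitting.

## Tumor growth and efficacy statistics

Growth follows the per-animal exponential model
`log10 V = a + b·day`; treatment acts through the ER level with

    d log10 V / dt = b0 − bkill·(1 − E(t)/e0)^gamma,

the simplest smooth link that reduces exactly to the exponential model
at vehicle. The trajectory integrates this slope by trapezoid on a
0.05-day grid (error orders of magnitude below caliper noise), with
`E(t)` linearly interpolated from the driving ER course.

Efficacy statistics implement the field's conventions:

* growth-rate fits floor volumes at 15 mm³ before the log transform —
  small residual masses are below reliable caliper resolution;
* `%TV change = (V_end − V_baseline)/V_baseline × 100`;
* TGI compares geometric-mean fold changes:
  `TGI% = 100·(1 − (GM_T − 1)/(GM_C − 1))`. The geometric mean matches
  the log-scale error structure of tumor volumes; with this convention
  an arm identical to control scores 0 %, stasis scores 100 %, and
  regression exceeds 100 % (reported unclipped). A control arm that
  did not grow (`GM_C ≤ 1`) makes the ratio meaningless, so the result
  is returned flagged rather than as a number;
* the hypothesis test is a one-tailed Welch (unequal-variance) t test
  on `log(V_end/V_baseline)`, alternative "treated grows less";
  a two-tailed variant is behind a flag. p values are per-comparison
  (no multiplicity correction by default, matching common reporting
  practice for designed dose groups);
* arms are aligned to the last day both have measurements; an animal
  ending early carries its last observation forward if within 7 days
  of that day and is excluded (and logged) otherwise.

Caliper volumes are taken as given in mm³; no length×width conversion
is applied to the two-diameter measurement convention.

## In vitro dose–response

Live counts (total − dead) are normalized to `(x − day0)/(untreated −
day0)`, so 0 is no net growth since seeding and 1 is untreated growth;
negative values mean net cell loss and are kept (they carry the
cytotoxicity information). The 4PL fit runs on log₁₀ concentration with
top/bottom initialized from the data extremes, the midpoint from the
concentration nearest half-range, hill = 1, and the midpoint bounded
within ±3 logs of the tested range. The reported IC₅₀ is the curve
midpoint (relative IC₅₀). A response range under 0.1 normalized units
is declared degenerate — no IC₅₀ is invented for a flat curve. Fits
require ≥ 6 concentrations spanning ≥ 2 logs. A fitted bottom below
−1e−6 is flagged cytotoxic; values within 1e−6 of zero are treated as
zero. The endpoint day (7 by default, 6 for fast-growing mutant lines)
is a field on the plate object and does not change the arithmetic.

## Signature scoring and ANCOVA

Expression values are standardized per gene across samples; the default
SD convention is population (divide by n), switchable to n−1. Constant
genes are dropped with a warning. The signature score is the unweighted
mean over signature genes of direction × z (+1 induced, −1 repressed);
scoring requires at least half the signature present (configurable).
This makes scores invariant to gene-wise affine transforms of the raw
matrix and antisymmetric under direction flips.

Note an inherent property of pooled z-scoring: a raw between-group
shift of δ (in units of the within-group SD) appears in the score as
`δ/√(1 + δ²/4)` for balanced groups, because the shift itself inflates
the pooled per-gene SD. The recovery tests assert this analytic value,
not δ.

Group comparison is one-way ANCOVA — `score ~ group + covariate` with a
partial F test on the group term; a constant or absent covariate
reduces it to one-way ANOVA. The default in vivo covariate is baseline
tumor volume. The shipped ER-activity gene list is an illustrative
synthetic placeholder (plausible estrogen-responsive genes), not a
curated signature; users supply their own two-column (gene, direction)
files.

## Reporting rules

Sensitivity: a model is sensitive iff its geometric-mean %TV change
from baseline is ≤ 100 %. This single threshold is the documented
criterion; the Welch p versus vehicle is reported alongside but does
not enter the call. Waterfall tables sort by descending %TV change with
deterministic lexicographic tie-breaks. Combination benefit requires
both p < α against the best monotherapy (lowest %TV change, ties broken
toward the endocrine arm, reflecting endocrine therapy's backbone role)
and a lower point estimate. Cross-agent summaries partition models into
dual-sensitive / dual-insensitive / discordant, which are exhaustive
and mutually exclusive by construction.

## Synthetic studies: what they emulate, and what they do not

The generator reproduces the observable structure of a dose-ranging
xenograft study: enrollment volumes uniform on 150–300 mm³,
twice-weekly caliper days (0, 3, 7, 10, 14, …), once-daily oral dosing
at 1/3/10/30 mg/kg against vehicle with 8 animals per arm, sparse PK
sampling over the first day, and ER time courses over the first two
days of dosing. Noise is multiplicative lognormal (median-1) on
volumes, concentrations and ER levels — these assays have
scale-proportional error — and additive Gaussian on log-expression.
Default CVs are 15 % (volumes, concentrations, ER) and SD 1.0
(log-expression): typical magnitudes for caliper, bioanalytical and
western-blot quantification; reported variability for such studies is
rarely published, so these are package choices.

Default ground truth: `ka` 1/h, elimination half-life ≈ 7 h, V/F
5 L/kg, `fu` 0.01; basal ER half-life 3 h, `smax` 9, `sc50` 0.4 nmol/L
free; vehicle growth 0.02 log10/day with `bkill` 0.06 so that sustained
deep ER loss produces regression. With these values the 10 mg/kg QD arm
averages ≈ 90 % ER suppression over a steady-state dosing interval,
i.e. deep degradation with only ~10 % ER remaining — the regime the
drug class targets. Because even the lowest default dose keeps free
drug above `sc50`, the efficacy dose–response is nearly saturated
across the default arms; the ER time-course dynamics between doses
still identify `sc50`, which is what the recovery tests exercise.

Determinism: one integer seed; each animal draws from its own stream
seeded by (study seed, arm index, animal index), so any per-arm subset
is reproducible in isolation. With all noise terms zero the outputs
equal the deterministic models to ≤ 1e−9 relative (1e−6 for ODE
outputs, the integrator tolerance).

What the generator does not emulate — and hence what passing tests do
not establish about real data: between-animal PK/PD parameter
variability (all animals share one truth), drop-out and humane-endpoint
censoring, measurement-day jitter, western-blot saturation and blotting
artifacts, correlated gene–gene expression structure, and batch
effects. Recovery rates measured here are therefore upper bounds on
real-study performance.

The planted-sensitivity cohort gives sensitive models a kill rate deep
enough for regression and insensitive models none at all, so the
planted class sits several noise SDs from the 100 % boundary and the
waterfall's class fractions reproduce the planted fractions exactly at
the default noise level — by design a check of the classification
plumbing, not of borderline discrimination.

## Problem sizes and runtime choices

The shipped analyses are sized for a laptop-class single core: 20-seed
sc50 recovery on the full 4-dose/8-animal design (~1 s simulate + ~1 s
fit per seed), 1000-seed half-life and test-calibration loops, 200-seed
4PL noise sweeps, and a 10-model demo cohort. These sizes give stable
Monte Carlo estimates (binomial SE ≈ 0.7 % at 1000 draws) while keeping
the whole suite in a few minutes.

## Known limitations

* The PK and ER-turnover structures are deliberately minimal; richer
  in vivo behavior (effect delay, receptor synthesis feedback,
  chromatin-bound ER pools) is not modeled.
* The ER→growth link `b0 − bkill·(1 − E/e0)^gamma` is a phenomenological
  bridge, not a mechanistic proliferation model.
* TGI's `(GM − 1)` ratio convention is one of several in use; compare
  conventions before benchmarking against other software.
* The sensitivity threshold (≤ 100 % %TV change) is a reporting
  convention; it is not a statistical test.
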