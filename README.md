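# serdstudy

Quantitative analysis of preclinical studies of selective estrogen
receptor degraders (SERDs) in ER⁺ breast cancer models — the chain from
plasma drug exposure, through drug-stimulated ER protein degradation, to
tumor growth inhibition in xenografts — together with the supporting
in vitro dose–response and transcriptional readouts. A synthetic-study
generator with known ground truth stands in for animal and expression
data, so every estimator in the pipeline can be validated end to end at
desk scale.

Intended users: DMPK/pharmacology modelers and computational biologists
running or analyzing SERD-class in vivo efficacy programs.

## What it computes

**Exposure.** One-compartment oral PK with first-order absorption
(Bateman function), linear superposition over repeated doses, and
free-fraction correction `Cu = fu·C`. Concentrations in nmol/L, times in
hours.

**ER degradation (the core model).** A stimulation-of-loss
indirect-response model for the receptor pool

```
dE/dt = ksyn − kout·(1 + smax·Cu/(sc50 + Cu))·E ,   ksyn = kout·e0 ,
```

where `E` is ER as a fraction of untreated baseline, `kout` the basal
degradation rate (basal half-life `ln2/kout`), `smax` the maximal
fold-stimulation of degradation and `sc50` the free-drug concentration
giving half-maximal stimulation — the in vivo degradation IC₅₀. Under
constant exposure the steady state is `E_ss = e0/(1 + smax·Cu/(sc50+Cu))`,
which the ODE solver is tested against. The package fits
`(kout, smax, sc50)` to multi-dose ER time courses, estimates half-lives
from decay data by log-linear regression, and computes the average ER
suppression over a steady-state dosing interval.

**Efficacy.** Per-animal exponential growth fits
`log10 V = a + b·day` (volumes < 15 mm³ floored to 15 mm³),
`%TV change = (V_end − V_baseline)/V_baseline × 100`, tumor growth
inhibition from geometric-mean fold changes
`TGI% = 100·(1 − (GM_T − 1)/(GM_C − 1))` (stasis = 100 %, regression
> 100 %), and one-tailed unequal-variance (Welch) t tests on
`log(V_end/V_baseline)` versus vehicle.

**In vitro.** Proliferation plates normalized so day-0 = 0 and untreated
endpoint = 1, then a four-parameter logistic fit on log₁₀ concentration
yielding IC₅₀, pIC₅₀ = −log₁₀(IC₅₀/M) and bottom-of-curve.

**Transcription.** Per-gene z-scoring of expression matrices, signature
scores as the mean of direction-weighted z values over a gene set, and
group comparison by one-way ANCOVA.

**Reporting.** Waterfall ordering by %TV change, sensitivity calls
(sensitive iff %TV change ≤ 100 %), cross-agent response proportions,
and combination-benefit calls against the best monotherapy.

## Worked example

Run the full pipeline (simulate a 4-dose study, fit the ER PK/PD model,
compute TGI, and report a 10-model cohort waterfall):

```bash
serdstudy report --out demo_out --seed 1
```

prints

```json
{
  "sc50_estimate_nM": 0.40702534658618483,
  "sc50_true_nM": 0.4,
  "tgi_by_arm": {
    "1mpk_qd": 133.25170932040945,
    "3mpk_qd": 134.13014767319447,
    "10mpk_qd": 133.71734866803766,
    "30mpk_qd": 133.56377446542785
  },
  "sensitive_fraction": 0.6,
  "planted_sensitive_fraction": 0.6
}
```

Reading this: the degradation potency refit from the noisy simulated ER
time courses (`sc50_estimate_nM`, 0.407 nmol/L) recovers the generating
value of 0.4 nmol/L within 2 %. All four dose arms show TGI above 100 %,
i.e. net tumor regression — at these exposures the free drug sits well
above `sc50` through the whole dosing interval, so ER suppression, and
with it the antitumor effect, is nearly saturated from the lowest dose.
The cohort waterfall calls 6 of 10 models sensitive, exactly the
fraction the generator planted. `demo_out/` holds the simulated tables
(`volumes.tsv`, `conc.tsv`, `er.tsv`), the fit, per-arm TGI, the ordered
waterfall and a run log; a fixed seed reproduces every file byte for
byte.

The same steps are available as library calls
(`simulate_study`, `fit_er_pkpd`, `tgi`, `waterfall`, …) and as
individual subcommands (`serdstudy simulate`, `fit-pk`, `fit-pkpd`,
`avg-suppression`, `tgi`, `growth-rates`, `dose-response`, `score`).

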