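# Methods

`crosspk` analyses phase-I IV-infusion crossover studies of the kind used
to characterise ceftazidime–avibactam pharmacokinetics and its potential
drug–drug interactions with metronidazole: noncompartmental analysis (NCA)
of plasma and urine profiles, geometric LS-mean ratio equivalence testing
against 80–125% limits, and the associated two-one-sided-tests (TOST)
power calculation. Because individual subject data from such trials are
not publicly deposited, the package ships a synthetic-study generator
whose designs, dosing calendars, sampling schedules and variability
structure reproduce the published study conditions; every downstream
stage is exercised and tested against that generator and against
closed-form oracles.

## Forward model (`pk_model`)

Disposition is an open one- or two-compartment linear model with
zero-order (constant-rate) input, solved in closed form as a sum of
exponentials. For a unit bolus the concentration is
`sum_i coef_i exp(-rate_i t)`; infusion curves and interval AUCs follow by
convolution, also in closed form, so the identities

* AUC(0–∞) = Dose / CL,
* cumulative urinary excretion over [0, ∞) = f_renal × Dose,
* linear superposition over repeated doses,

hold to machine precision and serve as independent oracles for the NCA
layer. Units are fixed: hours, mg, L, L/h, µg/mL. The infusion rate is
`amount / duration` with no lag time. The one-compartment model is the
default simulation engine (its closed forms are exact and simple); the
two-compartment model sits behind the same interface for multiphasic
profiles. A one-compartment calibration cannot match the observed Cmax
and AUC simultaneously for a 2-h infusion (real profiles are
multiphasic); the defaults privilege CL, AUC and terminal half-life,
which are the quantities the acceptance checks depend on, and understate
Cmax. This is a documented limitation of the simulator, not of the NCA
machinery.

Default calibrations (choices, not estimates — the source study is purely
noncompartmental): ceftazidime CL 7.0 L/h, t½ 2.7 h, renal fraction 0.95;
avibactam CL 12.0 L/h, t½ 2.5 h, renal fraction 1.0; metronidazole CL
4.35 L/h (500 mg / 115 µg·h/mL steady-state AUCτ), t½ 8.4 h, renal
fraction 0.1. V follows from V = CL·t½/ln 2.

A note on accumulation: the familiar ratio `1/(1 − e^(−λz τ))` is the
bolus-limit accumulation factor. For a 2-h infusion with τ = 8 h the
exact one-compartment steady-state accumulation is
`AUC(0–∞) / AUC_single(0–τ)`, which is materially larger (≈1.20 vs 1.147
for λz = 0.2567 h⁻¹) because less of the first dose's area falls inside
the first dosing interval. Tests use the exact expression as the oracle
for 2-h-infusion simulations and verify convergence to the bolus formula
as the infusion duration shrinks.

## Synthetic studies (`synthetic`, `designs`)

Three presets mirror the study conditions: a 16-subject 11-day
multiple-dose design (single dose Days 1 and 11, q8h Days 2–10; rich
sampling Days 1, 4 and 11; urine 0–2, 2–4, 4–8, 8–12, 12–24 h on Days 1
and 11); and two 3-way crossover interaction designs (n = 27 and n = 28,
each period 4 days with a single dose on Days 1 and 4 and q8h on Days
2–3 — 8 administrations per component per period — washout ≥ 48 h, all
six treatment orderings cycled over subjects). In the combined
metronidazole arm the 1-h metronidazole infusion precedes the 2-h
ceftazidime–avibactam infusion by 1 h, and sampling times follow the
published per-arm schedules. A `replicate_design` (same treatment in
every period) supports variance-component calibration checks.

Variability is generated hierarchically on the log scale:

* **between-subject** — a subject-level multiplier `exp(η)`,
  η ~ N(0, σb²), applied to clearance with volumes co-scaled;
* **within-subject** — an independent period-level multiplier of SD σw,
  applied the same way;
* **assay noise** — independent proportional noise `(1 + cv·z)` per
  measured concentration and urine amount.

Scaling CL and all volumes by a common factor leaves every rate constant
(hence half-life, tmax, profile shape) unchanged and multiplies the whole
concentration curve by the inverse factor. Consequently the within-subject
SD of log Cmax and of log AUC both equal σw exactly — the single-σw
parameterisation the power calculation assumes — and AUC/Cmax variation is
perfectly correlated within a period. (The source study estimated smaller
within-subject variability for AUC than Cmax; the simulator does not
reproduce that refinement, which makes its AUC contrasts slightly
conservative.) Interval urine amounts are invariant to the exposure
multipliers — higher clearance means proportionally lower AUC at equal
excreted mass — so mass balance holds for every subject-period, while
CLR = Ae/AUC varies with effective clearance, as it should.

Defaults: σb = 0.15 (geometric CV ≈ 15%, the magnitude of the published
between-subject CVs), σw = 0.2171 (ceftazidime), 0.2088 (avibactam, and
metronidazole by the "no greater" assumption), assay CV 5% (reported
assay precision was ≤ 7%). Sampling-time jitter is off by default
(`actual_time = nominal_time`); published tmax ranges of 2.00–2.02 h show
deviations were negligible. Day-1 predose samples are zero and therefore
BLQ. LLOQs: 0.0446 (ceftazidime), 0.010 (avibactam), 0.040 µg/mL
(metronidazole), after the assays' low calibration limits; values below
the limit are flagged BLQ with the numeric value withheld, the limit
itself is quantifiable. One master seed drives per-(subject, period,
analyte) `numpy` generator streams, so a fixed seed reproduces the output
CSVs byte for byte.

## NCA (`nca`)

* **Cmax/tmax** — maximum observed concentration; ties broken to the
  earliest time.
* **AUC** — linear-up/log-down trapezoids: a segment with `C2 < C1`, both
  positive, uses `Δt (C1−C2)/ln(C1/C2)`; otherwise the linear rule.
  Boundaries inside a segment (e.g. τ = 8 h between 7- and 11-h samples)
  are interpolated by the segment's own rule. AUC(0–τ) uses τ = 8 h on
  every analysis day, including Day 1 where sampling extends to 24 h.
* **λz** — OLS of ln C on t over the last k quantifiable points strictly
  after tmax, k = 3…8; the window with maximal adjusted R² wins, ties
  (within 1e-4) going to more points. Fits with R² < 0.8 or a nonnegative
  slope are not reportable.
* **Extrapolation** — AUC(0–∞) = AUC(0–last) + Clast/λz; when the
  extrapolated fraction exceeds 20%, AUC(0–∞), t½, CL and the linearity
  index are withheld. Cmax, tmax, AUC(0–τ), AUC(0–last) and CLR remain
  reportable, matching the parameter set the gating footnotes suppress.
* **BLQ policy** — leading BLQ samples enter the grid as zero; embedded
  and trailing BLQ samples are excluded from the AUC grid and the λz fit.
* **CL, CLR, t½** — CL = dose/AUC(0–∞); CLR = Σ urine amount over the
  collection span common to plasma sampling (0–24 h on profile days)
  divided by the plasma AUC over that span; t½ = ln 2/λz. In the combined
  arm each analyte's NCA clock starts at its own infusion, and urine
  interval boundaries are shifted by the same offset.
* **Derived ratios** — accumulation ratio AUCτ(ss)/AUCτ(Day 1); linearity
  index AUCτ(ss)/AUC(0–∞, Day 1).
* **Summaries** — geometric mean with geometric CV% = 100·√(exp(s²)−1),
  s the n−1 SD of the natural-log data; tmax as median (range); t½, CL,
  CLR as arithmetic mean (SD). Rounding (half-up; 3 significant figures
  for exposure, 1 d.p. for ratios/t½/CL, 2 d.p. for tmax) is applied only
  in the reporting layer.

## Equivalence and power (`equivalence`)

Each contrast (test vs reference treatment, per parameter and day —
AUC(0–∞) and Cmax on Day 1, AUC(0–τ) and Cmax on Day 4) is estimated on
the natural-log scale from within-subject differences. Subjects are
grouped by which periods carried test and reference; the treatment effect
is the unweighted mean of group means, which cancels period effects in
designs balanced over orderings, with pooled within-group variance and
residual df = n − G (falling back to the plain paired contrast, df =
n − 1, when grouping is degenerate). On complete balanced data this
coincides — exactly, as a test verifies against fixed-effects OLS — with
the treatment contrast of the mixed model with sequence, period and
treatment fixed effects and subject-within-sequence random effect.
Subjects missing either side of a contrast are excluded and counted. The
90% CI is `exp(effect ± t(0.95, df)·SE)`; "no interaction" is declared
iff every CI lies in the closed interval [80%, 125%].

Analytic TOST power treats the log-ratio estimate as N(log θ, σw²·2/n)
with an independent pooled variance on n − 2 df, and integrates the
bivariate noncentral-t acceptance region over the denominator chi
distribution (equivalent to Owen's Q functions); σw = 0 is handled as the
degenerate limit (power 1 strictly inside the limits, else 0). With
n = 24, σw = 0.2171, limits (0.8, 1.25), α = 0.05 and true ratio 1 the
power is 0.929. The simulated twin draws per-subject log differences with
variance 2σw² under a balanced two-ordering crossover and applies the
identical contrast estimator, vectorised over replicates; a test verifies
rep-for-rep identity of the vectorised decision with `ls_mean_ratio` on
assembled records.

## Pipeline and reproducibility (`pipeline`, `cli`, `config`)

`run_pipeline` chains simulate → NCA → derived ratios → interaction
analysis → power, writing the three study CSVs, per-profile NCA results,
formatted summary tables, a ratio table with the decision JSON, a power
report and a log of every gating event. The log carries no timestamps so
a rerun with the same config reproduces the output directory byte for
byte. The CLI (`crosspk simulate|nca|ddi|power|run`) is a thin layer over
these functions; `run` accepts a YAML config overridable by flags.

## Problem sizes and what the tests show

Unit and property tests run the generator at 2–6 subjects for structural
checks, 800–1000 subjects × 2 periods for variance-component recovery
(within-subject SD recovered within 5% at 2000 subject-periods), and
10,000–20,000 replicates for power/type-I Monte Carlo (MC SE < 0.005).
Passing tests demonstrate internal consistency against closed-form and
numerical oracles and fidelity to the published design and analysis
rules; they cannot validate the structural model against real multiphasic
profiles, assay calibration drift, sampling-time deviations, dropouts or
carryover, none of which the generator emulates (a subject-period
exclusion is represented simply by omitting the records).

## Known limitations

* One-compartment defaults understate Cmax for 2-h infusions (see above).
* The contrast estimator equals the mixed model only for balanced
  complete data; with unbalanced ordering groups it is a documented
  approximation, and the CI df convention (n − G) is a package choice.
* Power simulation assumes the balanced two-ordering layout; heavily
  unbalanced designs would need the full estimator per replicate.
* Urine assay LLOQ censoring is not modelled (amounts are continuous).
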