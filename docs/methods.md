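# Methods

## The comprehensive complication index

Every complication of a post-transplant course is graded with the
Clavien–Dindo classification (I < II < IIIa < IIIb < IVa < IVb < V, graded
by the invasiveness of the treatment required; V = death). The CCI maps the
multiset of graded complications to a 0–100 morbidity scale:

CCI = √(Σᵢ wCᵢ) / 2,

summing the weight of *every* occurred complication, including repeats of
the same treatment. The published per-grade calculator exposes only the
single-event index values (8.7, 20.9, 26.2, 33.7, 42.4, 46.2, 100), not the
weights inside the square root. We use the canonical weight table
{I: 300, II: 1750, IIIa: 2750, IIIb: 4550, IVa: 7200, IVb: 8550, V: 39940},
which reproduces all printed single-event values at one-decimal
half-away-from-zero rounding; an alternative inversion wC = (2·value)² can
be swapped in (`GradeWeightTable.from_single_event_values`), and any
user-supplied strictly increasing table is accepted.

Numerical conventions:

* **Death override.** √39940/2 = 99.92…, but the scale is defined to end at
  100 = death, so any grade V event forces the score to exactly 100.
* **Cap.** Weight sums exceeding the death weight (possible with many
  grade IV events) are capped at 100. Whether such courses should exceed
  "death = 100" is undefined in the source material; we hard-cap.
* **Rounding.** Scores are carried unrounded; only display/report values
  are rounded (half away from zero, one decimal), since it is unknowable
  whether downstream consumers of the web calculator used rounded values.
* **Timing window.** The score is intended to cover the first
  post-transplant hospitalization (events up to discharge). When event days
  are recorded, `compute_cci(..., day_cutoff=...)` enforces this; undated
  events are always kept.

Transplant-specific event translations (grade_clinical_event): EAD → II,
PNF → IVa, MOF → IVb, mild renal dysfunction (creatinine > 1.5 mg/dL
without dialysis) → I, RRT → IVa, myelotoxicity → I, death → V, and
retransplantation during the first hospitalization → IVa + IIIb (liver
failure plus reoperation), scored as a composite worth 54.2 on its own.

## Diagnostic evaluation

Graft loss (death or retransplantation) is dichotomized at a horizon
(90/365 days): event if loss occurred by the horizon, non-event if followed
beyond it loss-free. Patients censored loss-free before the horizon carry
no information about the binary endpoint and are excluded with a logged
count; the source analyses do not describe their handling, and this
complete-information choice is the simplest defensible one. (The same
applies to missing covariate data: the original maximum-likelihood
treatment of <10% missingness is not reproduced; fits are complete-case
with a logged count, and synthetic data are complete by construction.)

The AUC is computed as pairwise concordance with ties counting one half
(equivalently the trapezoidal ROC area), its standard error by the DeLong
placement-variance construction (standard for paired score comparisons;
asymptotically it reduces to Hanley–McNeil), and the 95% CI as
AUC ± 1.96·SE truncated to [0, 1]. A binary score such as the EAD flag
passes through the same machinery and yields the two-point trapezoid
(sens + spec)/2.

Cut-offs are score quantiles (default 25th/50th/75th/90th percentiles) by
linear interpolation at fractional rank 1 + (n−1)p — the common default of
statistical software; no formula is stated in the source. Test positivity
is score **strictly greater** than the cut-off; with heavily tied low
scores this strict convention is what makes the ninth-decile row's very
high specificity attainable. A `positive_if_equal` switch provides the ≥
convention. The DOR is reported without continuity correction — the printed
value 1149.4 from sens 53.5 / spec 99.9 is only consistent with the
uncorrected ratio — and boundary sens/spec (0 or 1) yields 0/∞ with a flag;
a Haldane-style +0.5 count correction exists but is off by default.

Baseline cohort comparisons follow the usual prescription: Mann–Whitney U
with the tie-corrected normal approximation (no continuity correction) for
continuous variables, two-sided Fisher's exact for 2×2 tables.

## Survival analysis

Kaplan–Meier product-limit curves and the k-sample log-rank test (χ² with
k−1 df) are delegated to lifelines; ties of events and censorings at one
time are resolved events-first. CCI strata use the fixed bands
[0, 12.2], (12.2, 29.6], (29.6, 47.3], (47.3, 84.9], (84.9, 100] — the
training-set quartiles/ninth decile frozen as published, closed on the
right so a patient exactly at 12.2 falls in the lowest band.

Cox proportional-hazards models are fitted by partial-likelihood
maximisation through the statsmodels PH machinery, Newton iterations
(tolerance 1e-8, ≤ 100 iterations). Tie handling is **Breslow** by default
— the default of the era's clinical software — with Efron as an option. A
zero-variance covariate cannot move the partial likelihood and is reported
with β = 0, HR = 1 (SE/p undefined) rather than crashing the fit; exactly
collinear pairs are rejected naming both members.

Backward-Wald selection: candidates are screened univariably (entry
p < 0.20), then the covariate with the largest Wald p-value is removed
while that p-value is ≥ 0.10 (the conventional removal default; the source
names the procedure but not the threshold), refitting after each removal.
MELD and D-MELD (= donor age × MELD) never enter one model; the pipeline
fits the two parallel models instead. Note a statistical fact about the
procedure itself: with three noise candidates, these thresholds retain each
noise covariate in ~8% of replicates, so "exactly the true model" appears
in about 78% of runs — the relevant guarantees, which the tests assert, are
that a genuinely associated covariate survives essentially always and that
per-noise retention stays near the nominal rate.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at configurable
scale, under a single integer seed (identical config + seed ⇒ identical
cohort).

**Complication profile.** Two laws are available. The plain law draws
independent Poisson counts per grade (death as a Bernoulli);
`poisson_rates_from_highest_grade_margins` solves its rates so the expected
highest-grade profile matches a target margin profile. The presets use a
hierarchical law instead: the patient's highest grade is drawn directly
from the published categorical margins — matching them exactly, including a
validation profile with essentially no complication-free patients, which is
infeasible for the independent-Poisson law — and Poisson co-occurring
events at or below that grade are added. The co-occurrence rates are the
free calibration parameters: they were tuned once, by simulation, against
the published median CCI (29.3 training-like, 24.2 validation-like) and
IQR, and frozen. Under the independent law the two targets cannot both
hold: margin-matching pins every rate and leaves the training median near
24, five points short.

**Covariates.** Donor age ~ normal (56 ± 20 training-like, 56 ± 17
validation-like, clipped to 16–95); MELD and BAR log-normal for the
training-like preset (medians 15 and 5) and normal for the
validation-like one (26 ± 4.4, 11 ± 3.7), matching the published
median/IQR shapes; D-MELD is donor age × MELD by definition; EAD is an
independent Bernoulli (40.3% / 16.7%). Covariates are independent of the
complication profile by default so that parameter-recovery tests are clean;
an optional gamma-frailty knob (a latent severity multiplier on both the
event rates and the hazard) introduces realistic confounding when wanted.

**Outcome.** Graft-loss times follow a Weibull proportional-hazards model
with linear predictor 0.044·CCI + ln(1.01)·(donor age − 57) +
ln(1.03)·(BAR − ref), i.e. HR ≈ 1.05 per CCI point and small donor-age/BAR
effects. The CCI entering the hazard is always *recomputed from the
generated events*; discrimination of CCI for graft loss is therefore an
emergent property, not an input. The baseline is Weibull with shape 0.55
(decreasing hazard — early post-transplant risk dominates) and scale 10⁵
days (training-like; 3·10⁵ validation-like), chosen once so that patients
with CCI = 100 are mostly lost within 90 days while low-CCI patients'
90-day/1-year loss fractions stay near the published single-digit
percentages. Censoring is administrative, uniform on 100–2600 days
(training-like; 700–2800 validation-like), giving a median follow-up in
the published 3.7–4.8-year range. Complication days are uniform on the
first 60 post-transplant days, clamped to the observed follow-up.

**What the generator does not emulate.** Only printed margins are matched:
the joint distribution of complications and pre-transplant covariates in
the real cohorts is unknowable from the publication. EAD is generated
independently of the grade-II events and of the outcome, so its synthetic
AUC hovers near 0.5 rather than the published 0.56–0.58; the same holds for
MELD/D-MELD/BAR beyond the small configured BAR effect. Stratum-level
survival in the real data is strongly non-log-linear in CCI (three low
strata nearly flat, then a cliff), whereas the generator is exactly
proportional-hazards in CCI; synthetic stratum survival therefore degrades
more smoothly. Passing tests consequently demonstrate correctness of the
estimators and emergence of the configured structure — not that real
transplant data look like this in every respect.

## Problem sizes used in the checks

The test and acceptance workloads are sized for a single CPU: preset margin
and median checks at n = 5000, hazard-ratio recovery as 50 replicates of
n = 2000 (the recovered CCI hazard ratio must land in [1.04, 1.06] in
≥ 90% of them), oracle-equivalence sweeps at n ≤ 50, and the end-to-end
pipeline examples at n = 150–1262. The analysis drivers default to the
published cohort sizes (1262 and 520).
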