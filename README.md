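# cci-lt — comprehensive complication index analysis for liver transplantation

`cci_lt` scores post-liver-transplant courses with the **comprehensive
complication index (CCI)** and evaluates that score — against MELD, D-MELD,
BAR and the EAD flag — as a predictor of 90-day and 1-year graft loss.

The CCI condenses *every* complication of a surgical course, graded by the
Clavien–Dindo classification, into one number on a 0–100 scale:

```
CCI = √(wC₁ + wC₂ + … + wCₓ) / 2
```

where each `wC` is the weight of one occurred complication (grade I…V). A
course with no complications scores 0; a course containing a grade V
complication (death) scores 100. A single complication of grade I, II,
IIIa, IIIb, IVa or IVb scores 8.7, 20.9, 26.2, 33.7, 42.4 or 46.2.
Transplant-specific events are translated before scoring: early allograft
dysfunction (EAD) counts as grade II, primary non-function and renal
replacement therapy as IVa, multiorgan failure as IVb, mild renal
dysfunction and myelotoxicity as grade I, and retransplantation during the
first hospitalization as the composite IVa (liver failure) + IIIb
(reoperation).

The package is aimed at clinical-outcomes researchers who want to

* compute CCIs from per-patient complication event tables (CSV),
* quantify a score's diagnostic ability for a dichotomized survival
  endpoint (ROC/AUC with DeLong standard errors, quantile cut-offs,
  sensitivity/specificity and the diagnostic odds ratio
  DOR = sens·spec / ((1−sens)(1−spec))),
* stratify Kaplan–Meier graft survival by CCI band (0–12.2, 12.3–29.6,
  29.7–47.3, 47.4–84.9, 85–100) with log-rank tests, and fit
  univariable/multivariable Cox models with backward-Wald selection, and
* generate fully synthetic cohorts with a CCI-driven proportional-hazards
  outcome (HR ≈ 1.05 per CCI point by default), so every analysis runs
  without access to patient-level data.

## Worked example

Score a course containing an EAD episode and a reoperation for bleeding:

```python
>>> from cci_lt import ComplicationEvent, ClavienDindoGrade, compute_cci
>>> course = [
...     ComplicationEvent("p1", ClavienDindoGrade.II, label="EAD"),
...     ComplicationEvent("p1", ClavienDindoGrade.IIIb, label="reoperation for bleeding"),
... ]
>>> compute_cci(course).display
39.7
```

39.7 is √(1750 + 4550)/2: both complications count, and the square root
keeps the cumulative score below the sum of the single-event values
(20.9 + 33.7).

Run the whole analysis on a synthetic cohort from the shell:

```
cci-lt run-all --preset training_like --n 1262 --seed 1 --outdir results/demo
```

which prints

```
best score at 90 d: cci (AUC 0.86)
best score at 365 d: cci (AUC 0.85)
reports written to results/demo
```

and writes the per-patient CCIs, one diagnostic table per horizon
(AUC ± SE with 95% CI per score, then sensitivity/specificity/DOR at the
quartile/ninth-decile CCI cut-offs), the five-stratum Kaplan–Meier summary
with the log-rank test, and the univariable plus backward-Wald
multivariable Cox tables. On this cohort the multivariable model retains
CCI (HR 1.04/point), donor age (HR 1.01/year) and BAR (HR 1.04/point) —
the CCI effect dominating by Wald statistic — and 1-year graft survival
falls from 93.1% in the lowest CCI band to 2.5% in the 85–100 band
(log-rank p < 10⁻²⁰⁰).

The same steps are laid out as a narrative under `analysis/`
(`01_simulate_cohorts.py` … `05_aged_donor_subgroup.py`): simulate a
training-like (n = 1262) and a validation-like (n = 520) cohort, score
them, derive the CCI cut-offs on the training-like cohort and validate them
on the other, run the survival models, and repeat the diagnostic comparison
in the aged-donor (≥ 70 years) subgroup.

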