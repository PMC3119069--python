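# curb65a

Derivation and evaluation of **CURB65-A**, a composite clinical risk score
for patients presenting with lower respiratory tract infection (LRTI):
community-acquired pneumonia (CAP), COPD exacerbation or acute bronchitis.
CURB65-A refines the three conventional CURB65 severity classes with two
cut-offs of the prognostic blood biomarker proadrenomedullin (ProADM),
yielding three risk classes with attached site-of-care recommendations.
The package is aimed at biostatisticians and clinical-epidemiology
researchers who want to reproduce, stress-test or extend this style of
biomarker-enhanced score derivation.

## The score

CURB65 awards one point each for

- **C**onfusion,
- **U**rea > 7 mmol/L,
- **R**espiratory rate ≥ 30 /min,
- **B**lood pressure: systolic < 90 mmHg or diastolic ≤ 60 mmHg,
- age ≥ **65** years,

and is collapsed into classes 0–1 / 2 / 3–5. ProADM (nmol/L) is split at
0.75 and 1.5 nmol/L (boundaries inclusive on the lower side). The
composite classes are:

| | ProADM ≤ 0.75 | 0.75 < ProADM ≤ 1.5 | ProADM > 1.5 |
|---|---|---|---|
| **CURB65 0–1** | I → outpatient | II → short hospitalization | III → inpatient |
| **CURB65 2** | II | II | III |
| **CURB65 3–5** | III | III | III |

The evaluation pipeline computes stratified event rates with Wald 95%
intervals, ties-corrected Mann–Whitney AUCs (DeLong standard errors, paired
DeLong test for the joint CURB65 + log-ProADM logistic model vs CURB65
alone), within-class Cochran–Armitage trend tests across ProADM categories,
Hosmer–Lemeshow decile calibration of within-class log-ProADM logistic
models, a spline-logistic smoothed risk curve, and the triage-reallocation
cross-tab (actual site of care vs recommendation).

Because the original patient-level data are not publicly deposited, the
package ships a seeded synthetic cohort generator (`curb65a.cohort`) whose
marginal and joint structure — class sizes, ProADM distribution, per-class
event probabilities, within-class biomarker–risk gradient — matches the
published derivation cohort of 1359 patients.

## Worked example

```
curb65a simulate --seed 7 -n 1359 -o demo
curb65a evaluate -i demo/cohort.csv -o demo/report
curb65a report -i demo/report
```

prints (abridged):

```
stratum         n   adverse_events  adverse_pct  ...  mortality_pct
Risk class I    300   10             3.33        ...   0.0
Risk class II   536   58            10.82        ...   3.73
Risk class III  523  129            24.67        ...  10.9
Total          1359  197            14.5         ...   5.67

-- adverse --
AUC curb65_class: 0.59 (0.55-0.63)
AUC curb65a_class: 0.68 (0.65-0.72)
AUC proadm: 0.73 (0.69-0.77)
combined model AUC 0.73 vs CURB65 0.59 (DeLong p = 1.6e-09)
```

Read: in this simulated cohort of 1359 patients, 30-day adverse-event risk
climbs from 3.3% in CURB65-A class I to 24.7% in class III (the configured
generator values are 3.9 / 8.6 / 21.6%; a single cohort of this size
scatters around them), and adding log-ProADM to the CURB65 score raises the
apparent AUC for adverse events from 0.59 to 0.73 with a paired DeLong
p ≈ 2 × 10⁻⁹. The triage cross-tab in the same bundle shows how many
actually hospitalized patients the composite score would redirect to
ambulatory care or a short stay.

The same pipeline runs on any cohort CSV with columns
`age,confusion,urea_mmol_l,resp_rate,sbp,dbp,proadm_nmol_l,diagnosis,death30,icu30,complication30,outpatient`
(booleans 0/1; `diagnosis` one of `CAP`, `COPD_exacerbation`, `bronchitis`,
`other`).

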