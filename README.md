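# oncogram

Scoring and clinical-concordance analysis for an ex vivo
chemosensitivity assay (Oncogramme-type) in advanced colorectal cancer.

Chemosensitivity and resistance assays expose a patient's primary tumor
culture to candidate chemotherapies and score drug-induced cell death,
aiming to predict which regimen the patient will respond to.  This
package implements the full analysis pipeline for such an assay and is
aimed at biostatisticians and assay developers validating one against
clinical outcomes:

1. **Scoring** — well-level live/dead/total cell counts become death
   fractions and the per-drug response ratio
   `r = (% dead, treated) / (% dead, untreated)`.
2. **Categorization** — the *method of percentiles*: within each
   treatment, `r` above the cohort's 75th percentile is sensitive (S),
   below the 25th resistant (R), otherwise intermediate (I); S and I
   collapse to the binary call "sensitive".
3. **Clinical coding** — received regimens (5-FU ± folinic acid,
   FOLFIRI, FOLFOX; biologics ignored) are matched to tested conditions,
   RECIST 1.1 outcomes (CR/PR/SD vs PD) collapse to responder /
   non-responder, and each (patient, regimen) pair with a determined
   assay result becomes a case.
4. **Concordance** — from the 2×2 table of clinical label × assay call:
   sensitivity TP/(TP+FN) and specificity TN/(FP+TN) with exact
   Clopper–Pearson 95 % CIs, overall agreement (TP+TN)/n, and Cohen's
   kappa (po−pe)/(1−pe) with the Fleiss–Cohen–Everitt asymptotic CI and
   Landis–Koch interpretation.
5. **Simulation** — a seeded synthetic-cohort generator with the study
   cohort's statistical structure (baseline mortality, per-drug ratio
   distributions, missing conditions, treatment switches, outcome links
   with configurable true sensitivity/specificity) for calibration,
   power and parameter-recovery experiments.

The package ships the 19-patient pilot cohort as a checksummed plain-CSV
fixture and reproduces its published principal and supplementary
analyses end to end.  See `docs/methods.md` for the model, conventions
and modelling choices.

## Worked example

```bash
oncogram reproduce-paper
```

prints (abridged):

```
- patients: 19
- experimental conditions: 74/76 successful (97.4 %)
- comparable cases: 22 from 18 patients

## Principal analysis (policy: any-progression)

|                | assay sensitive | assay resistant |
|----------------|-----------------|-----------------|
| responder      |              11 |               2 |
| non-responder  |               6 |               3 |

- sensitivity: 84.6 % (11/13), 95 % CI (54.55; 98.08)
- specificity: 33.3 % (3/9), 95 % CI (7.49; 70.07)
- agreement: 63.6 % (14/22), 95 % CI (40.66; 82.8)
- kappa: 0.1927 [95 % CI (-0.1966; 0.5819)], slight (Landis–Koch) / very weak (magnitude scale)
```

Reading: of 13 clinical responders, 11 were called sensitive ex vivo
(sensitivity 84.6 %), but only 3 of 9 non-responders were called
resistant (specificity 33.3 %); overall 14 of the 22 comparable cases
agree, and the chance-corrected agreement (kappa 0.19) is weak at this
cohort size.  The supplementary block repeats the analysis on the 13
patients with no treatment switch under the final-evaluation policy
(sensitivity 70.0 %, specificity 66.7 %, kappa 0.2973).

The same stages run on your own data (or a simulated cohort):

```bash
oncogram simulate --seed 42 --n-patients 25 --out-dir cohort/
oncogram score --wells cohort/wells.csv --out ratios.csv
oncogram categorize --ratios ratios.csv --out categories.csv
oncogram cases --treatments cohort/treatments.csv \
    --evaluations cohort/evaluations.csv --categories categories.csv \
    --out cases.csv
oncogram concord --cases cases.csv --out concordance.json
```

or from Python:

```python
from oncogram import (SimulationConfig, simulate_cohort, score_wells,
                      PercentileCategorizer, build_cases, concordance)

cohort = simulate_cohort(SimulationConfig(n_patients=25), seed=42)
ratios = score_wells(cohort.wells)
categories = PercentileCategorizer().fit_predict(ratios)
cases = build_cases(cohort.lines, cohort.evaluations, categories)
result = concordance(cases)
print(result.kappa.kappa, result.kappa.interpretation)
```

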