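# Methods

## The assay and its score

The package analyses a standardized ex vivo chemosensitivity assay for
advanced colorectal cancer.  A patient's primary tumor culture is split
into four monoplicate wells: an untreated control and three standard
regimens — 5-FU with folinic acid (FU_FA), FOLFIRI (5-FU + FA +
irinotecan) and FOLFOX (5-FU + FA + oxaliplatin).  After drug exposure,
live, dead and overall (nucleus-labelled) cells are counted over
randomly sampled microscope fields.

The per-well death fraction is `dead / total`, with *total* the overall
labelled population.  The source protocol counts live, dead and overall
populations separately, and does not state whether the overall count or
`live + dead` served as the denominator; we use the overall count (the
three counts are taken independently and `live + dead` may undercount),
and reject wells where `live + dead > total` as internally inconsistent.
Wells with fewer than `qc_min_cells` counted cells (default 1000, the
protocol's stated accuracy threshold) are flagged, not dropped.

The response score for a drug is the ratio of the treated death fraction
to the untreated death fraction.  A zero untreated fraction makes the
ratio undefined: the condition is flagged and excluded from
categorization rather than imputed.  Exactly one well per condition is
accepted per patient; duplicate wells raise an error instead of being
averaged, because the monoplicate design defines the assay.

## Method of percentiles

Within each treatment, cohort ratios are split at their 25th and 75th
percentiles: above the 75th is sensitive (S), below the 25th resistant
(R), between them — including exact ties with either threshold, since
the category definitions use strict "above"/"below" — intermediate (I).
The binary assay call gathers S and I as "sensitive", so only ratios
strictly below the 25th percentile read out resistant.

The percentile interpolation convention of the original analysis is not
recoverable (raw ratios are unpublished); the default is linear
interpolation between order statistics (numpy/spreadsheet "type 7"),
selectable via `percentile_method`, and published threshold pairs can be
injected verbatim as overrides.  Thresholds are per-treatment by
default; a pooled mode exists but is off by default because the
reference summaries are per-treatment.  Thresholds require at least 3
finite ratios.  The categorizer is exposed as a scikit-learn-style
estimator (`PercentileCategorizer`, fit/predict), so a reference cohort
can be fitted once and new patients categorized against it.

## Clinical coding and case building

Clinical follow-up is coded per evaluation with RECIST 1.1 outcomes;
responder means CR, PR or SD, non-responder means PD.  Received
chemotherapy lines map onto tested conditions by their cytotoxic
components only: {5-FU} or {5-FU, FA} → FU_FA; adding irinotecan →
FOLFIRI; adding oxaliplatin → FOLFOX.  Biologics (bevacizumab,
panitumumab) and radiotherapy never affect the mapping; a biologic-only
line maps to no condition and its evaluations are attributed to no
regimen.

Evaluation k is attributed to the regimen of cure k.  A cure with
neither chemotherapy nor a biologic (follow-up without treatment)
inherits the previous cure's regimen; this choice is validated against
the bundled cohort and is not load-bearing for any headline count.

How a multi-evaluation history collapses to one label is not specified
by the study text, so two named policies are implemented:

- **any-progression** (principal default): non-responder as soon as any
  attributed evaluation is PD;
- **final-evaluation** (supplementary default): the last attributed
  evaluation decides.

Each policy exactly reproduces the respective published
responder/non-responder splits (13/9 principal, 10/3 supplementary);
they are reverse-engineered conventions, clearly labelled as such.

A *case* is one (patient, distinct mapped regimen actually received)
pair with a determined assay category.  The supplementary subset keeps
patients whose first two cures are actual chemotherapy cures mapping to
the same condition (biologics ignored) with a determined assay result,
one case each.  Condition accounting plans 4 conditions per patient and
counts any not-determined condition as a failure.

## Concordance statistics

Cases are tabulated with clinical labels as rows and binary assay calls
as columns.  Sensitivity = TP/(TP+FN) (responders called sensitive),
specificity = TN/(FP+TN) (non-responders called resistant); both use
exact Clopper–Pearson intervals (statsmodels beta inversion).  Zero
margins yield explicitly undefined estimates (serialized as null with a
reason), never 0.

Cohen's kappa is `(po − pe)/(1 − pe)` with product-margin chance
agreement.  Its confidence interval uses the non-null large-sample
variance of Fleiss, Cohen and Everitt (1969) for unweighted kappa — the
formula that reproduces the published interval widths to all printed
decimals — with the simpler `po`-based variance available as an option
and documented as not matching.  The normal quantile is used at full
precision (1.959964 at 95 %), not rounded to 1.96.  Reported interval
bounds are clipped to [−1, 1] (kappa) and [0, 1] (proportions) only at
reporting time; raw bounds are retained.  Verbal interpretation is
emitted on two scales: the Landis–Koch bands (≤0 poor, ≤0.20 slight,
≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, else almost perfect) and
a magnitude scale (very weak < 0.2 ≤ weak < 0.4 ≤ moderate < 0.6 ≤
strong < 0.8 ≤ very strong) matching the wording some reports use; the
two disagree by design for small kappa.

## Bundled cohort fixture

No public deposit of the raw trial data exists, so the package ships
the published cohort tables as checksummed CSV: 19 patients' treatment
histories and per-evaluation outcomes, per-patient per-treatment
categories, per-treatment ratio summaries/thresholds, and flags for the
13-patient supplementary subset.  The source table marks received
treatments typographically (underlining), which cannot survive plain
text: an explicit `received` column encodes it, and the two rows whose
source typography is garbled (patients 08 and 09) carry an
`underline_ambiguous` flag; the adopted reading is the one consistent
with the published contingency counts.  The end-to-end reproduction
cross-checks the case set built from treatment histories against these
received markers and aborts on mismatch.

## Synthetic cohorts

The generator emulates the study's statistical structure so every
pipeline stage is testable without data access:

- **Untreated mortality**: Beta(9.6, 42.2) per patient — median 0.181,
  and the expected minimum/maximum of 19 draws bracket the observed
  0.082–0.309 range.
- **Drug effect**: per-treatment log-normal death ratios with medians
  1.343 / 1.633 / 1.787 and log-scale spreads 0.24 / 0.36 / 0.32,
  calibrated so the expected extremes of 19 draws (≈ ±1.8 σ) bracket the
  observed per-treatment ranges.  A configured median outside its
  minimum/maximum is rejected as an impossible calibration.
- **Counting**: per-well totals uniform on 1000–3000 cells; dead counts
  binomial given the latent fraction (a `counting_noise=False` switch
  replaces the binomial by rounding, for noise-free limit tests).
- **Histories**: first-line regimen shares 6/2/11 of 19, 2–3 cures,
  switch probability 4/18, concomitant bevacizumab rate 8/19, 2 of 76
  conditions missing — all matching the study's observed frequencies.
- **Clinical link**: per case, the responder label is drawn first
  (responder rate 13/22), then the latent assay truth: sensitive with
  probability `true_assay_sensitivity` given responder, resistant with
  probability `true_assay_specificity` given non-responder (defaults
  0.846 / 0.333, the study's estimates).  This direction makes the
  pipeline's sensitivity/specificity estimators unbiased for the
  configured values, which is what the recovery experiments measure.
- **Truth→ratio link**: within each treatment, the drawn ratio
  quantiles are permuted so truly-resistant cases hold the lowest ranks
  and truly-sensitive cases the highest, with non-case patients filling
  the middle; resistant quantiles are further compressed into the lower
  half of the below-quartile region.  The median and upper distribution
  are exactly preserved and the empirical 25th percentile is unchanged,
  while a guard margin keeps counting noise from flipping a constrained
  case across the quartile boundary.  This is the simplest mechanism
  consistent with cohort-relative percentile categorization — a
  modelling choice, not an empirical claim.
- **Outcomes**: PD appears only as the final evaluation of a
  non-responder's regimen run, so both response policies recover the
  intended label.

Randomness uses one root seed with named substreams per patient and
stage: enlarging the cohort never changes earlier patients' raw draws
(histories, baselines, quantiles), though the cohort-global rank
assignment — intrinsic to a percentile-relative truth — does depend on
the full cohort.  Identical seeds give byte-identical output files.

What the generator does *not* emulate: within-patient correlation of
drug responses beyond the shared untreated baseline, drift of tumor
chemosensitivity under therapy, informative missingness, lesion-level
RECIST measurement, or survival times.  Passing recovery tests
therefore show that the estimators are correct under the assumed
structure, not that the assay performs as modelled on real patients.

`recovery_experiment` simulates replicate cohorts, runs the full
pipeline on each, and reports per-metric Monte-Carlo mean, bias, RMSE,
MC standard error and CI coverage, plus the power of the kappa interval
to exclude 0.  The implied population kappa of a configuration is
computed in closed form from the responder rate and the truth link.

## Problem sizes and numerical choices

The test suite exercises the published 19-patient reproduction exactly;
distributional and recovery properties use desk-scale simulations
chosen to make Monte-Carlo error small relative to the asserted
tolerances: 200 replicate cohorts for calibration checks, 500
replicates of 100-patient cohorts for parameter recovery, 10,000 draws
per grid point for exact-interval coverage, and all 2×2 tables up to
n = 30 for the kappa oracle equivalence.  Degenerate inputs (empty
tables, zero margins, identical-margin tables with chance agreement 1,
all-identical ratios) raise typed errors or explicit undefined values
rather than NaNs.

## Known limitations

- The percentile convention and the response-collapsing policies are
  reconstructions constrained by the published counts, not documented
  author choices.
- Cohort-relative categorization means a patient's category depends on
  the cohort analysed; absolute sensitivity cut-offs are out of scope
  (the study defers them to a larger trial).
- The kappa interval is asymptotic; at n = 22 it is reported as
  published but is fragile, which is visible in the recovery
  experiments' coverage output.
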