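# Methods

## Scoring rules

The six triage tests are implemented as pure functions of a single patient
record; cohort context never affects a score.

* **RMI 1–4.** Multiplicative index `M × U × CA125` (`× S` for RMI 4) with
  the factor tables in the README. The ultrasound score is the count of
  five binary findings; the menopausal category is taken as stored on the
  record (the clinical classification rule — at least one year of
  amenorrhea, or age ≥ 50 after hysterectomy — belongs to data entry, not
  scoring). A missing tumour diameter makes RMI 4 an explicit error, never
  a silent `S = 1`.
* **ROMA.** Menopause-specific predictive index on natural-log biomarkers,
  mapped to a percentage through the logistic sigmoid (`scipy.special.expit`,
  so the value saturates at 0/100 without overflow and `ROMA(0) = 50`
  exactly). CA125 or HE4 reported as 0 is rejected rather than clamped:
  the index is undefined at 0 and silent imputation would hide a data
  problem. RMI tolerates CA125 = 0 (the product is simply 0).
* **Cutoffs.** 200 (RMI 1–3), 450 (RMI 4), 70 pmol/l (HE4), 11.4 %/29.9 %
  (ROMA pre/post). All inclusive — the ROMA rule is stated with "≥" and the
  others are applied identically for uniformity. Cutoffs are configuration
  (`Cutoffs`), not constants baked into the classifiers.
* **Censored HE4.** An assay result like ">1500" is stored as the bound
  with a censored flag. Scoring uses the bound itself, which is a
  conservative lower bound on the ROMA index; a censored bound *below* the
  HE4 cutoff is rejected as uninformative. No imputation is attempted.

## Evaluation

* **Outcome.** Malignant histology is the positive class; borderline
  tumours are grouped with benign. The epithelial flag on the record is
  authoritative for the epithelial-only subgroup, whose positives are
  restricted to epithelial malignancies while all negatives are retained
  (menopausal subgroups restrict both classes).
* **Proportion metrics.** Sensitivity/specificity/PPV/NPV are exact count
  ratios ×100. Confidence intervals are Wilson score intervals
  (`statsmodels`), chosen over Wald for small-count behaviour. A zero
  denominator (e.g. PPV when nothing is called high risk) yields an
  explicit "undefined" (`None`), never NaN.
* **ROC and AUC.** The empirical ROC sweeps the threshold through every
  distinct score; tied scores collapse to one point (a diagonal segment).
  The AUC is computed from midranks, so it equals exhaustive
  positive–negative pair counting *exactly* (ties ½), not merely to
  trapezoid tolerance; `sklearn.roc_auc_score` serves as an independent
  cross-check in the tests.
* **DeLong.** AUC variance is the placement-value estimator
  `S10/m + S01/n`; the paired z-test uses the variance of per-subject
  placement differences, which absorbs the covariance between two scores on
  the same patients. Both are hand-implemented (no installed Python package
  provides them) and validated against values frozen from R's pROC on a
  fixed dataset, a bootstrap percentile interval, and a swap-permutation
  oracle. A score compared against a monotone transform of itself has zero
  placement-difference variance; that degenerate case returns difference 0
  and p = 1. Pairwise AUC comparisons across the six tests are reported
  uncorrected at α = 0.05, with an optional Bonferroni flag (off by
  default) for the 15 pairs.
* **Rank/association tests.** Mann–Whitney is two-sided, exact when both
  groups have n ≤ 8 without ties, otherwise normal approximation with
  mid-rank tie correction (scipy). Chi-square is Pearson without continuity
  correction; tables with a zero margin are rejected.
* **Partial panels.** Records lacking a diameter are scored for the five
  diameter-free tests; RMI 4 evaluation uses only complete records and
  reports its effective n. Dropping whole records instead would silently
  change the denominators of every other test.

## Synthetic cohort generator

The generator emulates the 155-patient reference cohort whose summary
counts ship with the package: class mix 77.4 / 5.2 / 17.4 %
(benign/borderline/malignant), postmenopausal fractions 17.5 / 25 / 70.4 %
per class, and per-class HE4 medians 42.17 / 47.03 / 57.59 pmol/l.

* **Distributions.** Only medians and ranges of the reference cohort are
  known, so biomarkers and diameter are log-normal — positive and
  right-skewed, consistent with reference ranges spanning orders of
  magnitude — with log-means set to ln(median). Ages are clipped normals;
  ultrasound findings are independent Bernoullis per class (their joint
  distribution is unidentifiable from summary data); histology subtypes are
  categorical with the reference frequency table, and the epithelial flag
  follows the subtype (serous/mucinous/endometrioid adenocarcinomas plus
  fallopian-tube and peritoneal carcinomas count as epithelial, making the
  reference epithelial composition of 15/27 malignancies reachable).
* **Calibration choices** (quantities with no published value, chosen once
  from the reference medians/ranges and qualitative ordering): CA125
  log-medians 18 / 30 / 150 U/ml with log-SDs 1.0 / 1.0 / 1.5; HE4 log-SDs
  0.30 / 0.35 / 1.0; ultrasound finding probabilities rising from benign
  (0.25, 0.12, 0.08, 0.05, 0.01) to malignant (0.50, 0.70, 0.35, 0.50,
  0.30); diameter log-medians 6 / 7 / 9 cm; ages 38 ± 12, 38 ± 11, 51 ± 13
  years. These place composite-score medians in the reference order of
  magnitude (benign tens, malignant hundreds); exact replication of the
  composite medians or AUCs is *not* a contract, since the joint
  ultrasound–biomarker distribution is unidentified. The borderline class
  deliberately mimics benign biomarkers, reproducing the finding that no
  test separates benign from borderline.
* **Dependence.** CA125 and HE4 can be coupled within class through a
  Gaussian copula with a configurable Spearman rank correlation (default
  0); no other dependence is modelled. HE4 is right-censored at 1500 pmol/l
  with a censored flag, like the assay's reporting limit.
* **RNG contract.** One root `SeedSequence`; child streams per class and
  per variable, so adding a variable or resizing one class never perturbs
  other draws. `generate_cohort` is a pure function of its config (which
  contains the seed); identical configs give byte-identical CSV output.
* **What passing tests show.** Parameter recovery, determinism and the
  separation-knob trend validate the *pipeline*, not clinical performance:
  the generator has independent ultrasound findings, no within-class
  age–menopause coupling, and only optional biomarker correlation, so AUCs
  measured on synthetic cohorts characterise the simulation, not real
  adnexal-mass populations.

## Numerical and display conventions

* Scores are kept at full precision internally; reports round percentages
  to 1 decimal and AUCs to 3. Reference tables round half-up
  (56.25 → 56.3), provided as `round_half_up`.
* Wilson CI bounds are clamped to contain the point estimate (float
  round-off can otherwise push a boundary interval past 100 by ~1e-14).
* Units are fixed: CA125 U/ml, HE4 pmol/l, diameter cm; no auto-detection.
* Strict ROC monotonicity and the logistic's strict monotonicity are
  asserted only away from float saturation.

## Validation sizes

Null-simulation checks use 1000 replicates for DeLong CI coverage
(50 positives / 50 negatives per replicate) and 2000 replicates for
Mann–Whitney (50 / 50) and DeLong-paired (60 / 60) type-I error; parameter
recovery uses cohorts of 10^5. These sizes give Monte-Carlo standard errors
well inside the tolerances asserted (±2 and ±1.5 percentage points).

## Known limitations

* The generator models no tumour stage, survival, treatment or
  age–menopause dependence; subtype and biomarkers are independent given
  class.
* DeLong normal-theory intervals are slightly anticonservative at very
  small class sizes; subgroups with fewer than 5 positives are flagged in
  the logs as unstable.
* Only the six implemented tests are supported — no CA125-alone rule, no
  assay-specific ROMA recalibrations, no IOTA/ADNEX models, and no optimal
  cutoff search: published fixed cutoffs only.
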