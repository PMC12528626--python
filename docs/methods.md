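# Methods

`pmcdr` re-implements, as a reusable library, the analytic machinery needed
to ask whether gas-induced susceptibility artifacts on prostate DWI reduce
the cancer detection rate (CDR) of prostate MRI: an ordinal image-quality
(IQ) rubric with multi-rater consensus, a repeated coarsened-exact-matching
(CEM) scheme that builds optimal-IQ control groups for each artifact
severity, standardized-mean-difference balance diagnostics, a count-exact
decomposition of the CDR, and kappa agreement statistics.  A synthetic
cohort generator supplies data with the statistical structure the analysis
assumes, so the whole pipeline is testable without patient data.

## Image-quality model

Artifact severity is the proportion of the prostate obscured by
susceptibility artifact on low b-value DWI, scored in 10% increments and
collapsed to four ordered categories: optimal (0%), mild (10%), moderate
(20%), severe (>= 30%).  Multiple raters are combined by the ordinal
median; an even panel whose median falls between two categories is flagged
for adjudication and, by default, resolved to the *more severe* of the two
middle ratings (policy `worse`; `better` and `error` are available).  The
conservative default errs toward reviewing a series rather than ignoring
it; every adjudicated item is flagged so a human can re-decide.

When an examination has several DWI series, the examination-level grade is
the *best* (least severe) series grade — the reader interprets whichever
series shows the gland best.  Where both radiologist and model grades
exist for a series, the radiologist grade wins; the exam's source tag is
`radiologist` if any best-grade series was radiologist-graded.

## Matching

Confounders: age, PSA, pre-MRI biopsy status, facility.  Facility and
biopsy status are matched exactly.  Age and PSA are coarsened twice, into
6 quantile bins (narrow) and 3 quantile bins (wide), with a dedicated bin
for missing PSA at both levels.  Cut points are computed once per category
run on the union of targets and the initial pool, so neither side alone
defines the grid; intervals are right-closed.

Rounds: each target must receive exactly one control per round, searched
first among narrow-bin exact matches, then wide-bin; ties break uniformly
at random.  If any target has no candidate the whole round is discarded
and consumes nothing.  Because visiting order alone can make a feasible
round fail, a failed round is retried with a fresh seeded random order (10
attempts by default) before the procedure stops.  Matched controls leave
the pool between rounds, so `rounds_completed` equals the control:target
ratio exactly.  Categories are matched independently against fresh copies
of the optimal pool, so one control may serve several categories.
`max_rounds` defaults to 20.

Design notes: the narrow/wide fallback is applied to *both* age and PSA
(a two-tier coarsening); an alternative reading — age always 3 bins, PSA
always 6 — is not implemented.  All candidate bookkeeping uses
insertion-ordered structures and a single `numpy` Generator, so results
are bit-reproducible under a fixed seed.

## Balance

Continuous SMD: (m_t - m_c) / sqrt((s_t^2 + s_c^2)/2).  Multi-category
factors get one non-negative number via the Mahalanobis-type multivariate
standardized difference sqrt(d' S^-1 d) over the first k-1 categories,
with S the average of the two multinomial covariance matrices; for k = 2
this reduces to the usual binary-proportion SMD.  PSA's SMD uses
non-missing values only; the missingness proportion gets its own binary
SMD row.  |SMD| < 0.10 is reported as balanced.  Optional p-value columns
(Welch t, rank-sum, chi-squared) are descriptive companions, not the
balance criterion.

## Metrics and comparison

With PI-RADS >= 3 as the abnormal threshold:

    CDR = #(csPCa & PI-RADS>=3) / #exams
    AIR = #(PI-RADS>=3) / #exams
    PPV = #(csPCa & PI-RADS>=3) / #(confirmed & PI-RADS>=3)
    confirmation rate = #(confirmed & PI-RADS>=3) / #(PI-RADS>=3)

CDR = AIR x PPV x confirmation rate exactly on counts, and the identity
carries to target/control ratios, attributing a CDR change to reading
behaviour, biopsy yield, or biopsy uptake.  Zero-denominator components
are *absent*, never zero.

Uncertainty: Wilson score intervals for proportions; Katz log-method
intervals for risk ratios; Pearson chi-squared without continuity
correction on the detected/not 2x2 table.  Observations in the matched
cohort are treated as independent — matching-induced correlation is not
modelled, which mirrors the analysis this package reproduces and slightly
misstates CI width; both CI methods are isolated behind small functions
and swappable.

Zone subgroups: the PZ (TZ) subgroup drops examinations with *proven*
csPCa dominant in the other zone; benign and unconfirmed exams are always
retained.  Factor-vs-IQ association binarizes IQ to poor
(severe-moderate) vs acceptable (mild-optimal) and uses chi-squared /
Welch t / rank-sum according to the factor's type.

## Agreement

The multi-rater generalized kappa is the Fleiss-type estimator: observed
mean pairwise agreement against chance agreement from pooled category
marginals.  The model-vs-reader comparison uses Cohen's kappa with
quadratic disagreement weights (i-j)^2/(k-1)^2.  Verbal labels follow the
Landis-Koch bands (0.81-1.00 almost perfect … below 0 poor); values are
rounded half-up to two decimals before banding so every value falls in a
printed band.  Confusion matrices report proportions over the prediction
column.  Kappa confidence intervals are out of scope.

## Synthetic cohort

The generator emulates a three-facility cohort of ~13,000 examinations
performed with clinical suspicion of csPCa.  Defaults (units in
parentheses):

| parameter | default | why |
|---|---|---|
| `n_exams` | 12 947 | cohort scale of the analysis |
| `facility_probs` | .531/.215/.254 | facility mix of the control pool |
| `age_mean`, `age_sd` (years) | 65.5, 8.4 | cohort age summary |
| `psa_log_mean`, `psa_log_sd` | log 6.3, 0.5 | log-normal PSA with median 6.3, IQR ≈ [4.6, 9.0] |
| `psa_missing_frac` | 0.177 | PSA missingness rate |
| `iq_probs` | .528/.366/.098/.008 | series-level IQ mix (optimal→severe) |
| `series_per_exam_probs` | .946/.049/.005 | mean 1.06 series/exam |
| `cspca_base_prev` | 0.25 | csPCa prevalence |
| `detection_sensitivity_by_iq` | 0.95 ×4 | IQ-independent null by default; with prevalence 0.25 gives CDR ≈ 0.24 |
| `false_positive_rate_by_iq` | 0.28 ×4 | benign exams read PI-RADS ≥ 3, so AIR ≈ 0.45 |
| `confirmation_prob_given_pirads3plus` | 0.85 | biopsy uptake after an abnormal read |
| `systematic_biopsy_prob_given_pirads12` | 0.20 | systematic biopsy in PI-RADS 1–2 |
| `zone_pz_frac` | 0.8 | ~80% of csPCa is peripheral-zone dominant |
| `radiologist_review_probs_by_iq` | .10/.08/.15/1.0 | all severe series reviewed; small graded subsets elsewhere |

csPCa risk is logistic in standardized age and log-PSA plus facility
offsets — the simplest confounding structure matching must undo — with
the intercept calibrated by root-finding so the *marginal* prevalence
equals `cspca_base_prev` whatever the strengths.  Severe series'
obscured percentages put ~78% of mass on 30–40%, where real gas artifacts
concentrate.  An exam's planted category is the minimum over its series,
so the best-series rule recovers it exactly.

The generator deliberately simplifies real data: IQ is independent of
covariates (so pre-matching imbalance is mild unless constructed), every
diseased exam is eventually confirmed (so observed prevalence equals the
configured prevalence; in reality undiagnosed cancers are unobservable),
PI-RADS is collapsed to the {1,2} / {3,4} / {3,4,5} structure since only
the >= 3 threshold enters any metric, and patients have one exam each.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted effects — not that real cohorts are free of
residual confounding the four matched covariates cannot capture.

## Problem sizes and numerical choices

Simulation-based tests run at the cohort's own scale (12,947 exams per
replicate; 300 replicates for the coverage and recovery suites; 20,000
exams for the balance property).  Stochastic assertions use a >= 88%
empirical coverage floor for a nominal 95% interval (the matched design
leaves a little estimand noise from within-bin covariate mismatch on top
of binomial noise) and >= 90% for planted-effect recovery.
Quantile bins use linear-interpolation quantiles; duplicate cut points
collapse with a warning; constant variables degenerate to a single bin.
Division-by-zero situations (empty strata, zero control components,
all-one-category kappa) return absent values or warnings, never silent
zeros.

## Known limitations

- Matched-pair correlation is ignored in CIs and the chi-squared test.
- The pathology linkage window is abstracted to a boolean `confirmed`;
  date arithmetic (and multiple exams per patient) is out of scope.
- The CEM stopping rule beyond "a round failed after retries" is a design
  choice (`max_rounds`), as is retrying failed rounds with new orders.
- The multivariate categorical SMD is one reasonable convention among
  several; it is isolated in `balance.smd_categorical`.
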