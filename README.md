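# pmcdr

Does rectal gas ruin prostate MRI?  Susceptibility artifacts from bowel
gas distort diffusion-weighted imaging (DWI), the sequence that carries
most of the diagnostic weight for clinically significant prostate cancer
(csPCa, Grade group >= 2).  `pmcdr` implements the full analytic pipeline
for answering that question from routine clinical data: grade each DWI
series by the proportion of the prostate obscured (optimal 0%, mild 10%,
moderate 20%, severe >= 30%), take the best series per examination,
construct matched optimal-quality control groups by repeated coarsened
exact matching (CEM) on age, PSA, biopsy status and facility, and compare
cancer detection between groups through a count-exact decomposition

    CDR = AIR × PPV × pathological confirmation rate

where, at the PI-RADS >= 3 threshold, CDR is the cancer detection rate,
AIR the abnormal interpretation rate, PPV the positive predictive value
among biopsied abnormal reads, and the confirmation rate the biopsy
uptake.  The same identity holds for target/control ratios, so a CDR
deficit can be attributed to reading behaviour, biopsy yield, or biopsy
uptake.  Rater panels and model-vs-reader agreement are summarized with
Fleiss-type generalized kappa and quadratic weighted kappa with
Landis–Koch labels.

The package is aimed at imaging epidemiologists and MRI quality
researchers.  Because severity grades and clinical covariates are
patient data, a synthetic cohort generator with the same statistical
structure (three facilities, four IQ categories, ~25% csPCa prevalence,
~18% missing PSA, configurable IQ-dependent detection) makes every stage
runnable and testable out of the box.

## Worked example

```python
from pmcdr import ArtifactImpactModel, SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_exams=12947, seed=1))
results = ArtifactImpactModel(cohort).fit(seed=2)
print(results.summary())
```

```
Matched CDR comparison by DWI artifact severity
===============================================
Cohort: 12947 exams | CDR 0.24 | AIR 0.45
----------------------------------------------------------------------------
severity     n_t    n_c ratio   CDR_t  CDR_c      CDR ratio (95% CI)       p
----------------------------------------------------------------------------
mild         370   1110     3    0.26   0.27        0.95 (0.78–1.16)    0.64
moderate     214   1498     7    0.22   0.23        0.96 (0.74–1.26)    0.78
severe        99   1287    13    0.29   0.27        1.10 (0.80–1.52)    0.56
----------------------------------------------------------------------------
Max |SMD| after matching: 0.082 (balance threshold 0.10)
```

Each row is one artifact-severity stratum: `n_t` radiologist-graded
target examinations, `n_c` matched optimal-IQ controls (`ratio` controls
per target = completed matching rounds), the cancer detection rate in
each group, the target/control CDR ratio with its Katz 95% CI, and the
chi-squared p-value.  Here detection is IQ-independent by construction
(the generator's default), so all ratios sit near 1 and every
standardized mean difference is below the 0.10 balance threshold —
matching has removed the covariate imbalance without manufacturing a
detection effect.  `results.to_dict()` exposes the full per-stratum
metrics (AIR, PPV, confirmation rate, all CIs) and
`results.comparisons[...].balance_adjusted` the balance tables.

The same stages are scriptable from a shell:

```sh
pmcdr simulate --out-dir data --seed 1
pmcdr grade --series data/series.csv --exams data/exams.csv --out data/exams_graded.csv
pmcdr analyze --exams data/exams_graded.csv --out report.json --seed 2
pmcdr run --config run.yaml            # whole pipeline with a manifest
```

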