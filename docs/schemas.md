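# Input file schemas

Both tables are delimited text (comma by default, tab accepted), UTF-8,
with a header row.  Missing values are empty cells — never `0`, `NA` or a
sentinel.  A fixture pair lives in `docs/fixtures/`.

## exams.csv — one row per examination

| column | type | notes |
|---|---|---|
| exam_id | string | unique |
| patient_id | string | |
| age | number (years) | > 0 |
| psa | number (ng/mL) or empty | >= 0 when present |
| facility | `I` \| `II` \| `III` | |
| biopsy_status | `naive` \| `prev_benign` \| `unknown` | pre-MRI biopsy history |
| pirads | integer 1–5 | |
| confirmed | 0/1 | any pathological diagnosis in the one-year post-MRI window |
| cspca | 0/1 | Grade group >= 2; implies `confirmed = 1` |
| dominant_zone | `PZ` \| `TZ` \| `none` | `none` only when no lesion is reported |
| exam_iq | category name or empty | `optimal`/`mild`/`moderate`/`severe`; optional — recomputed from series when empty, never overwritten when present |
| iq_source | `radiologist` \| `model` or empty | provenance of `exam_iq` |

The pathology linkage window is abstracted into the `confirmed` boolean;
how examinations with several MRI dates per patient were linked to
pathology is the caller's responsibility.

## series.csv — one row per DWI series

| column | type | notes |
|---|---|---|
| exam_id | string | must resolve to an exam |
| series_id | string | |
| obscured_pct | integer or empty | obscured prostate proportion; multiples of 10 in [0, 100] |
| rater_categories | string or empty | `rater=category` pairs joined by `;`, e.g. `r1=mild;r2=severe` |
| model_category | category name or empty | the classification model's output |

At least one of the three IQ fields must be present per series.
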