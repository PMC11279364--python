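# metsdx

Diagnostic-accuracy pipeline for surrogate insulin-resistance and obesity
indices against rule-based metabolic syndrome (MetS) diagnosis, with a
synthetic survey-cohort generator so every stage is testable offline.

The pipeline: **cohort** (CSV ingestion, eligibility filtering, sex/age
stratification) → **markers** (SPISE, METS-IR, TG/HDL, TyG, LAP, VAI,
METS-VF, VAT, ABSI, BRI) → **criteria** (ATP III and IDF component-level
diagnosis) → **accuracy** (empirical ROC, Mann–Whitney AUC, Youden-optimal
cut-offs, Clopper–Pearson and bootstrap confidence intervals, paired
bootstrap comparison of correlated AUCs) → per-stratum accuracy tables.

## CLI

```sh
# synthetic cohort in the canonical CSV schema
metsdx simulate --n 10000 --seed 1 --out cohort.csv

# eligibility filtering with a per-rule removal log
metsdx filter --input cohort.csv --out-dir out/

# per-participant index panels and MetS labels
metsdx markers --input cohort.csv --out markers.csv
metsdx labels --input cohort.csv --out labels.csv --criteria atp3,idf

# full evaluation: one accuracy table per (criterion, sex x age stratum)
metsdx evaluate --input cohort.csv --seed 42 --bootstrap-reps 2000 --out out/

# paired-bootstrap AUC comparisons among each stratum's top-3 markers
metsdx compare --input cohort.csv --seed 42 --out comparisons.csv
```

`evaluate` writes `results.json`, `filter_log.json`, per-stage CSVs, and
one `table_*.csv` per criterion/stratum with columns
`Index, Cut-Off Point, AUC(95% CI), Se (%), Sp (%), PPV (%), NPV (%), LRP, LRN, Youden Index`,
rows sorted by descending Youden index. Runs are deterministic given
`--seed`, including all bootstrap intervals.

Input CSVs need a header with the canonical columns
`id,sex,age,weight_kg,height_m,bmi,wc_cm,sbp,dbp,chol_mgdl,hdl_mgdl,tg_mgdl,glu_mgdl,dx_diabetes,dx_hypertension,tx_tg,dx_chol`
(biochemistry in mg/dL; names remappable via a JSON `--column-map`).

## Library use

```python
from metsdx import accuracy, cohort, criteria, markers, pipeline, synthdata

records = synthdata.generate_cohort(synthdata.CohortSpec(n=10_000, seed=1))
kept, log = cohort.apply_eligibility(records)
kept = [cohort.derive_anthropometrics(r) for r in kept]
panel = markers.compute_panel(kept[0])
label = criteria.atp_iii(kept[0])

report = accuracy.evaluate_marker(scores, labels, B=2000, seed=7)
```

## Notes

- The Youden-index bootstrap re-maximizes the cut-off in every replicate
  and reports a basic (reverse-percentile) interval by default, because
  plain percentile intervals under-cover under cut-off re-selection; a
  fixed-cutoff variant and percentile intervals remain available.
- VAT is exp(METS-VF), so its ROC, AUC, and Youden rows are identical to
  METS-VF's by monotone-transform invariance — a property the test suite
  asserts exactly.
- The female VAI form defaults to the product of its three factors
  (matching the male form); a verbatim additive variant is available via
  `vai(..., women_as_printed=True)`.
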