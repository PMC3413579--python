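# linkenhance

Record-linkage enhancement of death reporting, as a reusable pipeline:

1. **records** — domain types and delimited-file I/O for a death-registration
   table and a linked-records table, plus ICD-10 cause-group membership
   (cancer C00–C97, cardiovascular I00–I99, external causes V01–Y98).
2. **units** — converts raw linked records into *units of information*:
   hospital (APD) episode rows are collapsed into stays via same-day
   discharge/admission adjacency or explicit transfer pointers; perinatal
   and birth-registration infant rows inherit a parent's reported status.
3. **enhancement** — classifies every death under three methods:
   *as reported* (the death registration alone), a *weight-of-evidence
   algorithm* (≥2 reporting units when ≥3 countable units exist, ≥1 when
   only 1–2 exist), and *at least one report* (any single report), plus a
   proportion-threshold variant.
4. **indicators** — stratified counts with percent increases, median age
   at death, and indirectly standardised mortality ratios (×100) with
   exact gamma (chi-square-equivalent) confidence intervals.
5. **sensitivity** — misclassification arithmetic: the per-10,000-record
   false-report rate implied by an excess count, closed-form expected
   spurious enhancements, and a false-positive-rate sweep through the
   full pipeline.
6. **synthetic** — a seeded generator for person-level cohorts with true
   status, per-source reporting sensitivities, transfer-chained hospital
   episodes, and injected linkage errors, so everything runs with no
   external data.

## CLI

```bash
# synthetic cohort (deaths.csv, linked.csv, truth.csv, linkage_log.csv)
linkenhance generate --seed 42 --n-deaths 2000 --out cohort/

# classify deaths under the three methods
linkenhance enhance --deaths cohort/deaths.csv --linked cohort/linked.csv \
    --out enhanced.csv

# report tables: counts + percent increases, median ages, SMRs
linkenhance indicators --deaths cohort/deaths.csv --enhanced enhanced.csv \
    --out report/

# false-positive sensitivity sweep
linkenhance sensitivity --fp-grid 0,1e-4,1e-3,1e-2 --seeds 5 --out sweep.csv
```

`generate` and `sensitivity` accept `--config config.yaml`
(see `linkenhance.synthetic.GeneratorConfig`; write a template with
`GeneratorConfig().to_yaml(path)`). `indicators` accepts `--rates` /
`--population` CSVs (`sex,age_band,rate|count`, five-year bands `0-4` …
`85+`); bundled synthetic defaults are used when omitted.

## File formats

Delimited text (comma default, tab accepted) with a header row.
Tri-state status fields are encoded `1` / `0` / empty for yes / no /
missing; dates are ISO-8601. `deaths.csv` columns:
`death_id,age_years,sex,remoteness,cause_icd10,reported_indigenous`.
`linked.csv` columns: `record_id,death_id,source,indigenous_flag,
mother_indigenous_flag,father_indigenous_flag,admit_date,discharge_date,
facility,transferred_from,transferred_to` (episode/transfer fields on
hospital rows only).

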