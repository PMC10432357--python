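# hipps

Pregnancy episode, outcome, and start-date (LMP) inference from
longitudinal, OMOP-style EHR event streams — plus a seeded synthetic cohort
generator with hidden ground truth so every stage is testable offline.

The package combines two independent episode-construction algorithms and a
start-date estimator:

* **HIP** (hierarchy/rule-based): outcome records are filtered through a
  priority hierarchy (live birth > stillbirth > ectopic > spontaneous
  abortion > induced abortion > delivery-record-only) with minimum-separation
  rules (e.g. ≥182 days between live births, ≥168 between stillbirths);
  "Gestation period, X weeks" records are split into gestation-based drafts
  whose starts are back-projected from the maximum recorded week; the two
  episode kinds are merged, with outcomes stripped when the recorded
  gestational age is implausible for the outcome (e.g. >301 days for a live
  birth).
* **PPS** (progression signature): a single deterministic scan over timed
  clinical concepts, each carrying an expected gestational-month window.
  An event extends the running episode when its elapsed time to at least one
  prior episode member (or its immediate predecessor) is consistent with
  both windows; otherwise a new episode starts only after a 60-day retry
  period. Cleanup removes >12-month episodes and persons with >5 episode
  starts in any 365-day window; outcomes are attached from a bounded search
  window after the last record.
* **Merge + concordance**: overlapping HIP/PPS episodes are paired by
  closest end dates and merged to interval unions with detection flags; a
  0–2 concordance score records cross-algorithm outcome agreement (±14
  days) and term-duration plausibility.
* **ESD**: week-level records back-project to point LMP candidates and
  ranged (GR3m) records to plausible intervals; outliers are removed only
  when they fall outside both the GR3m-interval intersection and the 1.5×IQR
  Tukey fences; the latest-dated retained week record supplies the point
  start, and the plausible-window width maps to a precision ladder
  (week … three-months, non-specific). A naive unfiltered baseline is
  included for comparison.
* **Annotation**: in-episode COVID-19 positivity/screening, the 60-day
  reinfection rule, three analysis cohorts (all episodes / outcome +
  month-or-better precision / outcome + score 2 + week precision),
  pre/post-March-2020 strata, ongoing-pregnancy flags, and a held-out
  concept overlap QC table.

## CLI

```bash
# generate a synthetic cohort (OMOP-lite CSVs + truth.csv + registry.json)
hipps simulate --seed 7 --n-persons 200 --out-dir sim/

# run the full inference pipeline
hipps run --input-dir sim/ --registry sim/registry.json --out-dir out/

# annotate and QC an episode table
hipps annotate --input-dir sim/ --episodes out/episodes.csv --out out/annotations.csv
hipps qc --input-dir sim/ --episodes out/episodes.csv --out out/qc.csv

# concept discovery (enrichment + timing statistics + curation template)
hipps discover --input-dir sim/ --cases cases.txt --controls controls.txt \
    --episodes out/hip_episodes.csv --out-dir disc/

# write the bundled fixture concept registry for editing
hipps registry-init --out registry.json
```

`out/` contains `episodes.csv` (final episode table), `hip_episodes.csv`,
`pps_episodes.csv`, `annotations.csv`, `esd_diagnostics.csv`, audit-trail
CSVs of dropped records, and `manifest.json` (config hash, input row
counts, stage timings). Identical inputs and configuration produce
byte-identical data outputs.

## Concept registry

All concept classifications (outcome categories, gestation-week concepts,
progression/GR3m/held-out timing windows, COVID test/diagnosis sets) and
every rule constant (separation matrix, term-duration windows, retry
period, days-per-month) live in a JSON registry
(`hipps.concept_registry`). The bundled fixture covers every role; apart
from the estriol window (months 3.75–5.5) its timing windows are documented
stand-ins, so site-specific concept sets can be dropped in without code
changes.

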