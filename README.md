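# stag2loop

Analysis toolkit for the chromatin-contact consequences of **STAG2 loss in
Ewing sarcoma**. Ewing tumors are driven by the EWS::FLI1 fusion
transcription factor, which turns GGAA microsatellites — chained runs of
the GGAA motif, "long" when more than four motifs (*n* > 4) — into de novo
enhancers. Cohesin-STAG2 helps connect these enhancers to target promoters;
its loss rewires promoter contacts and expression, and a STAG2-loss
expression signature marks patients with worse outcome.

The package implements the bespoke computations of that analysis as a
tested, composable pipeline, exercisable end-to-end on synthetic data with
planted ground truth:

* **`repeats`** — GGAA/TTCC repeat-run scanning (maximal chaining with a
  ≤ 5 nt inter-motif gap), peak annotation by longest run, and the
  blacklist + *q* ≥ 5 peak filter.
* **`chipcal`** — spike-in calibrated ChIP normalization via the occupancy
  ratio **OR = (W<sub>m</sub>·IP<sub>h</sub>)/(W<sub>h</sub>·IP<sub>m</sub>)**
  and per-peak log2 fold changes.
* **`contacts`** — sparse 3-kb binned contact matrices with on-target
  downsampling, bait-row normalization, distance-decay (observed/expected)
  normalization, and per-loop O/E strength.
* **`loops`** — read/score filtering of loop calls, consensus sets over
  four cell lines, common/gained/lost classification (≥ 3-of-4 → common;
  proficient-only → lost; knockout-only → gained), loop-length strata.
* **`metaplot`** — anchor-centered ± 500 kb local O/E pileups stratified by
  repeat length and cohesin co-occupancy.
* **`integration`** — gene classes (GGAA peak at the promoter "P", or
  looped to distal long/short repeats), per-gene contact-change labels,
  cohesin/CTCF loop gene selection, rank-based group comparisons.
* **`signature`** — directed signature from two DEG contrasts (FDR < 0.05,
  concordant sign), extreme-phenotype centroids (per-gene cohort max/min),
  k-means patient classification initialized at those centroids, PCA, and
  Kaplan–Meier / Cox proportional-hazards survival comparison.
* **`synth` / `study`** — generators for every input with planted truth
  (repeat runs, calibration counts, power-law contact matrices with
  planted loops, call tables, survival-linked cohorts).

## Worked example

Simulate a planted study and run the full pipeline on its files:

```bash
stag2loop simulate --outdir demo/in --seed 11
stag2loop run-study --indir demo/in --outdir demo/out --seed 11
```

which prints:

```
loop classes: {"common": 4, "gained": 2, "lost": 1}
gene classes: {"none": 5, "distal_long": 3, "P": 2, "distal_short": 2}
Two-group Cox proportional-hazards comparison
  groups: signature-like (n=60), signature-different (n=60)
  HR (signature-like vs signature-different): 3.390 [2.152, 5.341]
  p = 1.41e-07
```

Reading the output: of the seven planted promoter loops, four are called in
at least three of the four cell lines (common), two only in the STAG2
knockout clones (gained) and one only in the STAG2-proficient lines (lost)
— exactly the planted presence patterns. The twelve genes fall into the
planted enhancer classes: two with a GGAA-bearing EWS::FLI1 peak at the
promoter (P), three looped to distal long repeats, two to distal short
repeats, five with neither. The 120-patient cohort splits 60/60 and the
signature-like group carries a fitted hazard ratio of 3.39 (95% CI
2.15–5.34), recovering the planted hazard ratio of 3 within its confidence
interval. Written outputs include `gene_classes.tsv`,
`contact_changes.tsv`, `loops_classified.tsv` (with per-loop O/E strengths
and log2 KO/WT changes), `signature.tsv`, `cohort_labels.tsv` and
`survival_summary.json`.

The same stages are available as library calls (`stag2loop.repeats.scan_runs`,
`stag2loop.contacts.normalize`, `stag2loop.signature.classify_cohort`, ...)
and as focused subcommands (`scan-repeats`, `classify-loops`, `normalize`,
`loop-strength`, `pileup`).

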