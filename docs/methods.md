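# Methods

`stag2loop` implements the computational chain used to relate the loss of
cohesin-STAG2 in Ewing sarcoma to changes in enhancer–promoter contacts and
to patient outcome. This note records the models and procedures each module
implements, the parameters that matter, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## GGAA microsatellite scanning (`repeats`)

EWS::FLI1 binds the GGAA motif; chained motif runs act as neoenhancers, and
runs of more than four motifs ("long", *n* > 4) bind the oncoprotein far
more strongly than short runs (1 ≤ *n* ≤ 4). A run is a maximal chain of
non-overlapping motif occurrences in which the gap between the end of one
motif and the start of the next is at most `max_gap` (default 5 nt). GGAA
cannot overlap itself, so the left-to-right occurrence list is unique and
greedy chaining provably yields maximal runs.

Choices the motif definition leaves open, exposed as flags:

* **Strand** — by default both GGAA and TTCC (the reverse-strand motif) are
  scanned and reported per strand; a peak's `best_n` is the maximum over
  both. `strand_mode="forward"` restricts to GGAA. The microsatellite is
  double-stranded, so "both" is the default.
* **Gap metric** — the inter-motif distance is measured end-of-motif to
  start-of-next (edge-to-edge), the most literal reading of "distance
  between motifs".
* **Peak overlap** — a run annotates a peak when they share ≥ 1 bp.

Peak quality filtering retains unique peaks with −log10 *q* ≥ 5 that do not
intersect a blacklist (≥ 1 bp overlap excludes).

## Spike-in ChIP calibration (`chipcal`)

Calibrated ChIP-seq spikes a fixed fraction of foreign chromatin (mouse,
nominally 5%) into each sample. The occupancy ratio

    OR = (Wm · IPh) / (Wh · IPm)

(W = input reads, IP = immunoprecipitated reads; h/m = target/spike-in
genome) converts depth-normalized coverage to a scale on which global
occupancy changes survive normalization. "Normalized by coverage" is
interpreted as rescaling covered (non-zero) bins to mean 1 before applying
the OR; a per-million convention would differ only by a constant factor.
Per-peak differential signal is `log2((meanA + pc)/(meanB + pc))` over the
peak's bins with pseudocount `pc = 0.1` on the calibrated scale (guards
empty peaks, which report exactly 0).

## Contact matrices (`contacts`)

Contacts live on a genome-wide tiling into fixed bins (3 kb default), with
capture-bait (promoter) bins flagged. Raw matrices are upper-triangular
sparse counts.

* **Downsampling.** Library depth is equalized on the on-target fraction:
  pixels touching ≥ 1 bait bin are subsampled without replacement
  (multivariate hypergeometric over pixel counts) to exactly the minimum
  on-target total across conditions; off-target pixels are subsampled
  without replacement at the same global rate. Support never grows.
  Bin-level bait contact totals stand in for probe-level read accounting,
  the same quantity at matrix resolution.
* **Row normalization.** Each bait row is divided by its total, making rows
  comparable between baits of different capture efficiency. Positive rows
  sum to exactly 1; empty rows stay empty. Bait–bait pixels appear in both
  rows of the directed representation.
* **Distance-decay (O/E) normalization.** The expected value at bin
  distance *d* is the mean row-normalized value at *d* over bait rows only,
  computed per chromosome with unobserved (zero) positions counted in the
  denominator — matching the row-sum semantics, where zeros dilute a row.
  Inter-chromosomal pixels have no distance and are dropped. A distance
  observed in a single row position trivially normalizes to 1.
* **Loop strength** is the O/E value at the loop's single (bait, other-end)
  pixel — the default; a window variant is deliberately not provided, since
  anchors live on the same 3-kb grid as the calls. Differential strength is
  `log2((sKO + ε)/(sWT + ε))` with ε = 10% of the median positive strength
  across both conditions (the published log-ratio plots state no
  pseudocount; a data-scaled ε keeps absent pixels finite without swamping
  real signal). Replicate conditions are merged by pixel-wise count
  addition before normalization.

Normalization is scale-invariant: multiplying a raw matrix by any positive
scalar leaves the row-normalized and O/E results unchanged.

## Loop filtering and classification (`loops`)

Calls are kept with ≥ 5 reads (inclusive) and score > 3 (strict). Loop
identity across the four cell lines (Parental, WT clone, KO1, KO2) is exact
(bait_bin, oe_bin) equality on the shared grid — fuzzy anchor matching
would introduce unstated parameters. The consensus sets are loops called in
both STAG2-proficient lines (WT set) or both knockout clones (KO set);
within their union, the presence pattern over (P, WT, KO1, KO2) decides:

| pattern                  | label        |
|--------------------------|--------------|
| ≥ 3 of 4 lines           | common       |
| (1,1,0,0)                | lost         |
| (0,0,1,1)                | gained       |
| anything else in the union | unclassified |

Loops present in exactly two lines straddling conditions (e.g. P + KO1)
belong to neither consensus set and are excluded downstream. Loop length is
the midpoint-to-midpoint distance of the anchor bins; the default size
strata are < 80 kb, 80–800 kb (the cohesin-loop range), 800 kb–1 Mb, and
> 1 Mb (inter-TAD).

## Local pileups (`metaplot`)

A pileup averages, over a set of anchor bins, the square O/E window of
± `pad` (default 500 kb) around the diagonal at each anchor. Numerical
choices: pixels absent from the sparse matrix are imputed at 1 (the
expected value) rather than 0 — capture matrices are zero-dominated and
zero-imputation would bias every mean downward; windows crossing a
chromosome end are dropped entirely rather than padded (partial windows
would weight anchors unevenly), with the usable-anchor count reported; the
pad is truncated to whole bins (166 per side at 500 kb / 3 kb); log2 is
applied after averaging. Stratified pileups group anchors by repeat-length
class and cohesin co-occupancy and report the per-stratum anchor count.

## Gene-level integration (`integration`)

Promoters default to TSS ± 2 kb when the annotation carries no explicit
promoter intervals (capture designs define their own fragments, which are
not part of the inputs here); a gene's bait bins are the flagged bins its
promoter touches, and loops are pooled across them. Classes:

* **P** — a GGAA-bearing peak (best_n ≥ 1) overlaps the promoter;
* **distal_long / distal_short** — otherwise, a classified promoter loop
  reaches a bin bearing a peak with *n* > 4 / 1 ≤ *n* ≤ 4 (precedence
  P > distal_long > distal_short);
* **none** — neither.

Direct EWS::FLI1 targets are genes with |log2FC| strictly > 0.5 after
oncogene knockdown. Per-gene contact change: all relevant loops lost →
"lost"; all gained → "gained"; otherwise the mean differential strength
decides with a dead-band of |Δlog2| ≤ 0.25 ("common"); beyond it, "down" or
"up". The dead-band is a configurable default — the published category
boxplots print no threshold. Cohesin/CTCF gene selection keeps non-target
genes with ≥ 1 promoter loop whose anchor bins both overlap cohesin peaks
and at least one overlaps a CTCF peak. Group expression comparisons use
the Mann–Whitney U test (two groups) or Kruskal–Wallis (more), reporting
medians and quartiles per group.

## Signature and survival (`signature`)

The STAG2-loss signature is the set of genes significant (FDR < 0.05,
strict) in both the patient contrast and the cell-clone contrast with
concordant log2FC sign, which becomes the gene's direction. Classification
of an independent cohort works on the cohort's native log-expression scale
without per-gene standardization, because the extreme centroids are defined
on raw dataset values: the KO model takes each up-gene's cohort maximum and
each down-gene's minimum, the WT model the opposite. Two-group k-means
(Euclidean, Lloyd iterations to convergence) starts from those two
centroids; samples in the cluster whose converged centroid is nearer the KO
model are "signature-like". Assignment ties break toward the WT cluster
(conservative: a sample must be strictly nearer the KO side to be flagged).
The Lloyd loop is implemented in-package so the tie-break is explicit;
tests cross-check it against scikit-learn's k-means from the same
initialization.

Survival uses the Kaplan–Meier estimator per group and a two-group Cox
proportional-hazards fit (lifelines), reporting the hazard ratio of
signature-like vs signature-different with its 95% CI and p-value. PCA of
signature expression (gene-centered SVD, the largest-magnitude loading of
each component made positive for reproducibility) visualizes the split.
`flag_wtstar` identifies wild-type samples whose whole transcriptome
clusters with mutant samples: 2-group k-means on the top two principal
components, flagging WT samples in the cluster holding the MUT majority; a
MUT tie yields no flags. This is one defensible algorithmic reading of a
selection that could also be done by eye on a PCA plot.

## Synthetic data (`synth`, `study`)

The generators emulate the statistical structure of each input with planted
truth, so every stage can be verified offline:

* **Genomes** carry GGAA runs of specified motif count and gap (T-filled)
  at recorded coordinates; the i.i.d. background (GC fraction 0.4 default)
  is patched free of GGAA/TTCC occurrences, so planted run counts are
  unambiguous and scanner recovery can be asserted exactly.
* **Calibration counts** are Poisson draws at a stated depth with 5%
  spike-in chromatin and 10% IP efficiency; the OR estimator recovers the
  planted ratio to O(1/depth).
* **Contact matrices** have expected counts `base_count · d^(−α)` for bin
  distances 1 ≤ d ≤ `max_dist_bins` (defaults 600 and 200), planted loop
  pixels multiplied by per-condition folds ≥ 1, and optional Poisson noise.
  With noise off the float expectations are returned unrounded, and when
  every bait sits at least `max_dist_bins` from its chromosome ends all
  bait rows share one distance profile, making the O/E of a loop-free
  matrix exactly 1 — the self-normalization identity the tests assert at
  1e-9. A planted pixel itself enters the per-distance mean, so its O/E is
  slightly below its fold, by O(1/n_bait_rows).
* **Loop calls** emit each planted loop per cell line with a detection
  probability; reads default to 5 + NegBin(2, 0.3) and scores to
  3 + Gamma(2, 1) — heavy-tailed like real call tables, always passing the
  filter so that sub-threshold records are planted deliberately
  (`fail_frac`). The score distribution is a recorded convention, not an
  inference: published calls state only the > 3 threshold.
* **Cohorts** shift signature genes by ± effect (default 2 on log2 scale)
  in signature-like patients with N(0, noise_sd) noise; survival is
  exponential with baseline hazard 0.01/day multiplied by the hazard ratio
  for signature-like patients, and censoring is uniform over a follow-up
  horizon solved so the expected censored fraction equals `censor_rate`.

`study.generate_study` wires all of these into one consistent 2.7-Mb,
3-kb-binned scenario: 12 genes covering every enhancer class, 7 loops
covering every contact-change label, expression contrasts whose concordant
significant genes form a 5-gene signature, and a 120-patient cohort at
hazard ratio 3 with 20% censoring. The defaults are the noise-free
configuration in which every planted label is recovered with zero errors;
`noise`, `detect_prob` and `noise_sd` degrade the inputs realistically.

What the generators do **not** emulate: read-level data (no FASTQ,
alignment, duplicate or peak/loop calling — their outputs are consumed or
simulated), chromatin-state structure in the background sequence,
matrix-balancing artifacts, trans contacts, batch effects between cohorts,
and non-proportional hazards. Passing tests therefore certify the
correctness of the computations on inputs with the assumed statistical
shape, not robustness to upstream artifacts in real sequencing data.

## Problem sizes

The bundled study uses one 900-bin chromosome, ~160k-pixel matrices, 120
patients; pileup checks use a 5400-bin chromosome with 50 anchors; survival
calibration uses 100 replicate cohorts of 150 patients. These sizes make
every property sharp (binomial/Poisson standard errors well inside the
asserted tolerances) while the whole suite runs in well under a minute per
module.

## Known limitations

* Loop identity is exact bin-pair equality; anchors drifting by one bin
  between conditions would fragment consensus sets.
* O/E expected values are estimated per distance from bait rows only; with
  few bait rows, planted or real enrichments tilt the expected estimate
  (quantified above).
* The cohesin/CTCF anchor test uses bin-level peak overlap, so peaks
  anywhere in a 3-kb anchor bin qualify it.
* `flag_wtstar` and the patient classifier assume two clusters; cohorts
  with finer substructure are outside the model.
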