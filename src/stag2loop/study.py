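"""An internally consistent synthetic study exercising the whole pipeline.

:func:`generate_study` plants, on one 2.7-Mb chromosome binned at 3 kb:

* GGAA repeat runs of known length inside EWS::FLI1 peak intervals — at two
  promoters (gene class "P") and at distal bins reached by promoter loops
  (classes "distal_long" / "distal_short" by run length);
* promoter loops with per-condition enrichment folds encoding lost, down,
  common, up, and gained contact changes upon STAG2 loss, emitted both as
  per-cell-line call tables and as raw contact matrices;
* cohesin/CTCF-anchored promoter loops for two genes that are not
  EWS::FLI1 targets;
* expression contrasts (EWS::FLI1 KD, STAG2 KO, STAG1 KO, patient) whose
  concordant significant genes form a directed signature; and
* a patient cohort in which signature-like expression carries a planted
  proportional-hazards survival disadvantage.

The planted truth (gene classes, contact-change labels, loop patterns,
cohort labels) is recorded alongside, so downstream recovery can be checked
exactly in the noise-free configuration (the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .contacts import BinTable, ContactMatrix, make_bin_table
from .synth import (
    PlantedLoop,
    SimTruth,
    _patch_background,
    _run_sequence,
    generate_cohort,
    generate_contact_matrices,
    generate_loop_calls,
)

BIN_SIZE = 3000
CHROM = "chr1"
N_BINS = 900

# gene plan: (gene_id, tss_bin, enhancer_class, contact_change or None)
_GENES = [
    ("GP1", 220, "P", None),
    ("GP2", 240, "P", None),
    ("GL1", 260, "distal_long", "lost"),
    ("GL2", 300, "distal_long", "down"),
    ("GL3", 350, "distal_long", "gained"),
    ("GS1", 400, "distal_short", "common"),
    ("GS2", 430, "distal_short", "up"),
    ("GC1", 470, "none", "down"),
    ("GC2", 500, "none", "gained"),
    ("GN1", 560, "none", None),
    ("GN2", 590, "none", None),
    ("GN3", 620, "none", None),
]

# loops: (gene_id, bait_bin, oe_bin, fold_wt, fold_ko)
_LOOPS = [
    ("GL1", 260, 330, 4.0, 1.0),
    ("GL2", 300, 380, 5.0, 2.0),
    ("GL3", 350, 160, 1.0, 4.0),
    ("GS1", 400, 460, 4.0, 4.0),
    ("GS2", 430, 520, 2.0, 5.0),
    ("GC1", 470, 550, 5.0, 2.0),
    ("GC2", 500, 650, 1.0, 4.0),
]

# GGAA-bearing EWS::FLI1 peaks: (anchor_bin, n_motifs) — n > 4 is "long"
_GGAA_PEAKS = [
    (220, 6),  # GP1 promoter
    (240, 2),  # GP2 promoter
    (330, 6),  # GL1 other end
    (380, 7),  # GL2 other end
    (160, 6),  # GL3 other end
    (460, 3),  # GS1 other end
    (520, 2),  # GS2 other end
]

_COHESIN_BINS = [470, 550, 500, 650]
_CTCF_BINS = [550, 500]

# decoy peaks exercising the q / blacklist filter (no GGAA runs inside)
_DECOY_LOWQ_BINS = [60, 80]
_DECOY_BLACK_BINS = [100, 120]


@dataclass
class StudyData:
    """Everything :func:`generate_study` plants, inputs and truth together."""

    genome: dict[str, str]
    bin_table: BinTable
    peaks: pd.DataFrame
    blacklist: pd.DataFrame
    cohesin: pd.DataFrame
    ctcf: pd.DataFrame
    genes: pd.DataFrame
    loop_calls: dict[str, pd.DataFrame]
    matrices: dict[str, ContactMatrix]
    contrasts: dict[str, pd.DataFrame]
    cohort_expression: pd.DataFrame
    survival: pd.DataFrame
    truth: dict
    planted_loops: list[PlantedLoop] = field(default_factory=list)


def _peak_interval(anchor_bin: int) -> tuple[int, int]:
    return anchor_bin * BIN_SIZE + 1100, anchor_bin * BIN_SIZE + 1500


def _build_genome(rng: np.random.Generator) -> tuple[dict[str, str], list]:
    chrom_len = N_BINS * BIN_SIZE
    probs = [0.3, 0.2, 0.2, 0.3]
    seq = rng.choice(np.array(list("ACGT")), size=chrom_len, p=probs)
    runs = []
    spans = []
    for anchor_bin, n_motifs in _GGAA_PEAKS:
        run = _run_sequence(n_motifs, 0)
        start = anchor_bin * BIN_SIZE + 1200
        end = start + len(run)
        seq[start:end] = list(run)
        spans.append((start, end))
        runs.append((CHROM, start, end, n_motifs, "+"))
    patched = _patch_background(seq, spans, rng)
    return {CHROM: "".join(patched)}, runs


def _expression_contrasts(rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    gene_ids = [g for g, *_ in _GENES]
    efkd = {"GP1": -1.5, "GP2": -1.2, "GL1": -1.8, "GL2": -1.6, "GL3": -1.4,
            "GS1": 1.0, "GS2": 0.8, "GC1": 0.1, "GC2": -0.1,
            "GN1": 0.0, "GN2": 0.05, "GN3": -0.05}
    stag2 = {"GP1": -0.1, "GP2": 0.1, "GL1": -2.0, "GL2": -1.5, "GL3": 2.0,
             "GS1": -0.2, "GS2": 0.5, "GC1": -1.8, "GC2": 1.7,
             "GN1": 0.0, "GN2": 0.1, "GN3": -0.1}
    stag2_fdr = {g: (1e-4 if abs(v) > 1.0 else 0.6) for g, v in stag2.items()}
    stag1 = {g: rng.normal(0, 0.05) for g in gene_ids}
    # patient contrast: concordant with the STAG2-KO cell contrast for the
    # signature genes, null elsewhere
    patient = {g: (stag2[g] * 0.8 if stag2_fdr[g] < 0.05 else rng.normal(0, 0.05))
               for g in gene_ids}
    patient_fdr = {g: (1e-3 if stag2_fdr[g] < 0.05 else 0.7) for g in gene_ids}

    def table(lfc: dict, fdr: dict | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": [lfc[g] for g in gene_ids],
                "fdr": [1e-3 if fdr is None else fdr[g] for g in gene_ids],
            }
        )

    return {
        "efkd": table(efkd, {g: (1e-4 if abs(v) > 0.5 else 0.8) for g, v in efkd.items()}),
        "stag2ko": table(stag2, stag2_fdr),
        "stag1ko": table(stag1, {g: 0.9 for g in gene_ids}),
        "patient": table(patient, patient_fdr),
    }


def generate_study(
    seed: int = 0,
    noise: float = 0.0,
    detect_prob: float = 1.0,
    noise_sd: float = 0.0,
    n_patients: int = 120,
    hr: float = 3.0,
    censor_rate: float = 0.2,
    decay_exp: float = 1.0,
) -> StudyData:
    """Generate the full planted study; defaults are the noise-free setting.

    With the defaults every downstream stage recovers the planted truth
    exactly; ``noise`` (Poisson counts on matrices), ``detect_prob`` and
    ``noise_sd`` (cohort expression noise) degrade the inputs realistically
    while leaving the recorded truth unchanged.
    """
    rng = np.random.default_rng(seed)
    genome, runs = _build_genome(rng)

    bait_positions = {CHROM: [tss_bin * BIN_SIZE + 1500 for _, tss_bin, *_ in _GENES]}
    bin_table = make_bin_table({CHROM: N_BINS * BIN_SIZE}, BIN_SIZE, bait_positions)

    peak_rows = []
    for anchor_bin, _ in _GGAA_PEAKS:
        s, e = _peak_interval(anchor_bin)
        peak_rows.append((CHROM, s, e, 10.0))
    for b in _DECOY_LOWQ_BINS:
        s, e = _peak_interval(b)
        peak_rows.append((CHROM, s, e, 2.0))
    for b in _DECOY_BLACK_BINS:
        s, e = _peak_interval(b)
        peak_rows.append((CHROM, s, e, 10.0))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "q"])
    blacklist = pd.DataFrame(
        [(CHROM, b * BIN_SIZE, (b + 1) * BIN_SIZE) for b in _DECOY_BLACK_BINS],
        columns=["chrom", "start", "end"],
    )

    def bin_bed(bins: list[int]) -> pd.DataFrame:
        return pd.DataFrame(
            [(CHROM, b * BIN_SIZE + 500, b * BIN_SIZE + 2500) for b in bins],
            columns=["chrom", "start", "end"],
        )

    cohesin = bin_bed(_COHESIN_BINS)
    ctcf = bin_bed(_CTCF_BINS)

    genes = pd.DataFrame(
        [(g, CHROM, tss_bin * BIN_SIZE + 1500, "+") for g, tss_bin, *_ in _GENES],
        columns=["gene_id", "chrom", "tss", "strand"],
    )

    planted_loops = [
        PlantedLoop(bait, oe, {"WT": fwt, "KO": fko})
        for _, bait, oe, fwt, fko in _LOOPS
    ]
    loop_calls = generate_loop_calls(
        planted_loops, detect_prob=detect_prob, seed=int(rng.integers(2**31))
    )
    matrices = generate_contact_matrices(
        bin_table,
        decay_exp=decay_exp,
        planted_loops=planted_loops,
        noise=noise,
        seed=int(rng.integers(2**31)),
        max_dist_bins=200,
    )

    contrasts = _expression_contrasts(rng)

    signature = pd.DataFrame(
        {
            "gene_id": ["GL1", "GL2", "GL3", "GC1", "GC2"],
            "direction": ["down", "down", "up", "down", "up"],
        }
    )
    cohort_expr, survival, cohort_labels = generate_cohort(
        n_patients=n_patients,
        n_genes=60,
        signature=signature,
        effect=2.0,
        noise_sd=noise_sd,
        hr=hr,
        censor_rate=censor_rate,
        seed=int(rng.integers(2**31)),
    )

    truth = {
        "planted_runs": [list(r) for r in runs],
        "gene_classes": {g: cls for g, _, cls, _ in _GENES},
        "contact_changes": {g: cc for g, _, _, cc in _GENES if cc is not None},
        "loop_patterns": {
            f"{bait}-{oe}": [int(v) for v in
                             PlantedLoop(bait, oe, {"WT": fwt, "KO": fko}).lines().values()]
            for _, bait, oe, fwt, fko in _LOOPS
        },
        "signature": signature.to_dict("records"),
        "cohort_labels": cohort_labels.to_dict(),
        "hazard_ratio": hr,
        "ctcf_cohesin_genes": ["GC1", "GC2"],
        "n_peaks_pass_filter": len(_GGAA_PEAKS),
    }

    return StudyData(
        genome=genome,
        bin_table=bin_table,
        peaks=peaks,
        blacklist=blacklist,
        cohesin=cohesin,
        ctcf=ctcf,
        genes=genes,
        loop_calls=loop_calls,
        matrices=matrices,
        contrasts=contrasts,
        cohort_expression=cohort_expr,
        survival=survival,
        truth=truth,
        planted_loops=planted_loops,
    )


def write_study(study: StudyData, outdir) -> None:
    """Serialize a study to plain-text files consumable by the CLI."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_fasta(study.genome, out / "genome.fa")
    sio.write_bed(study.peaks, out / "peaks.tsv")
    sio.write_bed(study.blacklist, out / "blacklist.tsv")
    sio.write_bed(study.cohesin, out / "cohesin.tsv")
    sio.write_bed(study.ctcf, out / "ctcf.tsv")
    sio.write_bin_table(study.bin_table, out / "bins.tsv")
    for cond, m in study.matrices.items():
        sio.write_pixels(m, out / f"pixels_{cond}.tsv")
    for line, calls in study.loop_calls.items():
        sio.write_tsv(calls, out / f"calls_{line}.tsv")
    sio.write_tsv(study.genes, out / "genes.tsv")
    for name, df in study.contrasts.items():
        sio.write_tsv(df, out / f"contrast_{name}.tsv")
    sio.write_tsv(
        study.cohort_expression.rename_axis("gene_id").reset_index(),
        out / "cohort_expression.tsv",
    )
    sio.write_tsv(study.survival, out / "survival.tsv")
    sio.write_truth(study.truth, out / "truth.json")
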