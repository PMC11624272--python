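"""File-level pipeline driver: from study inputs to recovered labels.

Reads the plain-text inputs a study directory provides (genome FASTA, peak
and blacklist BED, bin table, per-cell-line loop calls, contact matrices,
gene annotation, expression contrasts, cohort expression and survival) and
runs every stage in order, writing the derived tables next to each other.
This is what the command-line interface wraps, and what end-to-end truth
recovery is asserted against.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as sio
from .contacts import differential_strength, loop_strengths, normalize
from .integration import (
    assign_enhancer_class,
    contact_changes_for_genes,
    select_ctcf_cohesin_genes,
    select_direct_targets,
)
from .loops import CELL_LINES, classify_loops, filter_calls
from .repeats import annotate_peaks, annotations_to_frame, filter_peaks
from .signature import (
    build_models,
    classify_cohort,
    intersect_degs,
    survival_compare,
)


def run_study_pipeline(indir, outdir, seed: int = 0) -> dict:
    """Run the full analysis on a study directory; returns the key outputs.

    Writes annotated_peaks.tsv, loops_classified.tsv, gene_classes.tsv,
    contact_changes.tsv, ctcf_cohesin_genes.tsv, signature.tsv,
    cohort_labels.tsv and survival_summary.json under ``outdir``.
    """
    ind, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    genome = sio.read_fasta(ind / "genome.fa")
    peaks = sio.read_bed(ind / "peaks.tsv")
    blacklist = sio.read_bed(ind / "blacklist.tsv")
    bin_table = sio.read_bin_table(ind / "bins.tsv")
    genes = sio.read_tsv(ind / "genes.tsv")

    # 1. peak filtering and GGAA annotation
    kept = filter_peaks(peaks, blacklist, q_min=5.0)
    annotated = annotations_to_frame(annotate_peaks(kept, genome))
    sio.write_tsv(annotated, out / "annotated_peaks.tsv")

    # 2. loop filtering and classification
    calls = {
        line: filter_calls(sio.read_tsv(ind / f"calls_{line}.tsv"))
        for line in CELL_LINES
    }
    classified = classify_loops(calls, bin_table)

    # 3. contact normalization and differential loop strength
    oe = {}
    for cond in ("WT", "KO"):
        m = sio.read_contact_matrix(ind / "bins.tsv", ind / f"pixels_{cond}.tsv",
                                    condition=cond)
        oe[cond] = normalize(m)
    s_wt = loop_strengths(oe["WT"], classified)
    s_ko = loop_strengths(oe["KO"], classified)
    classified["strength_wt"] = s_wt
    classified["strength_ko"] = s_ko
    classified["delta_log2"] = differential_strength(s_ko, s_wt)
    sio.write_tsv(classified, out / "loops_classified.tsv")

    # 4. gene-level integration
    gene_classes = assign_enhancer_class(genes, annotated, classified, bin_table)
    sio.write_tsv(
        gene_classes.rename_axis("gene_id").reset_index(), out / "gene_classes.tsv"
    )
    contact_changes = contact_changes_for_genes(
        genes, classified, classified["delta_log2"], bin_table
    )
    sio.write_tsv(
        contact_changes.rename_axis("gene_id").reset_index(),
        out / "contact_changes.tsv",
    )
    direct = select_direct_targets(sio.read_tsv(ind / "contrast_efkd.tsv"))
    ctcf_genes = select_ctcf_cohesin_genes(
        genes, classified, sio.read_bed(ind / "cohesin.tsv"),
        sio.read_bed(ind / "ctcf.tsv"), bin_table, direct,
    )
    sio.write_tsv(
        pd.DataFrame({"gene_id": sorted(ctcf_genes)}), out / "ctcf_cohesin_genes.tsv"
    )

    # 5. signature derivation, cohort classification, survival
    signature = intersect_degs(
        sio.read_tsv(ind / "contrast_patient.tsv"),
        sio.read_tsv(ind / "contrast_stag2ko.tsv"),
    )
    sio.write_tsv(signature, out / "signature.tsv")
    cohort = sio.read_tsv(ind / "cohort_expression.tsv").set_index("gene_id")
    model = build_models(cohort, signature)
    labels = classify_cohort(cohort, model, seed=seed)
    sio.write_tsv(labels.rename_axis("sample_id").reset_index(),
                  out / "cohort_labels.tsv")
    surv = sio.read_tsv(ind / "survival.tsv").set_index("sample_id")
    result = survival_compare(
        labels, surv.loc[labels.index, "time_days"], surv.loc[labels.index, "event"]
    )
    summary = {
        "hazard_ratio": result.hazard_ratio,
        "ci_lower": result.ci_lower,
        "ci_upper": result.ci_upper,
        "p_value": result.p_value,
        "n_per_group": result.n_per_group,
    }
    with open(out / "survival_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    return {
        "annotated_peaks": annotated,
        "loops_classified": classified,
        "gene_classes": gene_classes,
        "contact_changes": contact_changes,
        "ctcf_cohesin_genes": ctcf_genes,
        "signature": signature,
        "cohort_labels": labels,
        "survival": result,
    }
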