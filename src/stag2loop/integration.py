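"""Gene-level integration of binding, looping, and expression.

Genes are tied to EWS::FLI1-bound GGAA elements either directly (a
GGAA-bearing peak overlapping the promoter, class "P") or through a
classified promoter loop to a distal peak-bearing bin (class "distal_long"
or "distal_short" by the repeat length at the other end, with precedence
P > distal_long > distal_short). Direct oncogene targets are genes
deregulated after EWS::FLI1 knockdown (|log2FC| > 0.5). Per-gene contact
changes upon STAG2 loss are summarized from the loop classification and the
differential O/E strengths (lost / down / common / up / gained), and group
expression differences are assessed with the standard rank tests
(Mann-Whitney for two groups, Kruskal-Wallis for more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .contacts import BinTable

PROMOTER_FLANK = 2000  # bp each side of the TSS
DEADBAND = 0.25  # |mean delta log2| below which contacts count as unchanged

ENHANCER_CLASSES = ("P", "distal_long", "distal_short", "none")
CONTACT_CHANGES = ("lost", "down", "common", "up", "gained")


def promoter_intervals(genes: pd.DataFrame, flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """Promoter = TSS +/- flank unless explicit promoter bounds are given."""
    if {"promoter_start", "promoter_end"}.issubset(genes.columns):
        out = genes[["gene_id", "chrom", "promoter_start", "promoter_end"]].rename(
            columns={"promoter_start": "start", "promoter_end": "end"}
        )
        return out
    if "tss" not in genes.columns:
        raise ValueError("gene table needs 'tss' or promoter_start/promoter_end")
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "start": (genes["tss"] - flank).clip(lower=0),
            "end": genes["tss"] + flank,
        }
    )


def gene_bait_bins(genes: pd.DataFrame, bin_table: BinTable,
                   flank: int = PROMOTER_FLANK) -> dict[str, list[int]]:
    """Bait bins overlapping each gene's promoter interval.

    Genes whose promoter touches no bait bin map to an empty list (they can
    receive no capture loop and end up class "none").
    """
    promoters = promoter_intervals(genes, flank)
    bins = bin_table.bins
    out: dict[str, list[int]] = {}
    for rec in promoters.itertuples(index=False):
        grp = bins[(bins["chrom"] == rec.chrom) & (bins["is_bait"])]
        hit = grp[(grp["start"] < rec.end) & (rec.start < grp["end"])]
        out[rec.gene_id] = [int(b) for b in hit["bin_id"]]
    return out


def select_direct_targets(contrast: pd.DataFrame, lfc_min: float = 0.5) -> set[str]:
    """Genes deregulated after EWS::FLI1 knockdown: |log2FC| strictly > lfc_min."""
    if "log2fc" not in contrast.columns:
        raise ValueError("contrast table lacks a log2fc column")
    return set(contrast.loc[contrast["log2fc"].abs() > lfc_min, "gene_id"])


def _peak_tree(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, n) for s, e, n in zip(grp["start"], grp["end"], grp["best_n"])
        )
    return trees


def _bin_peak_best_n(peaks: pd.DataFrame, bin_table: BinTable) -> dict[int, int]:
    """Max best_n of annotated peaks overlapping each bin (bins with peaks only)."""
    trees = _peak_tree(peaks)
    out: dict[int, int] = {}
    for rec in bin_table.bins.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = tree.overlap(rec.start, rec.end)
        if hits:
            out[int(rec.bin_id)] = max(h.data for h in hits)
    return out


def assign_enhancer_class(
    genes: pd.DataFrame,
    annotated_peaks: pd.DataFrame,
    classified_loops: pd.DataFrame,
    bin_table: BinTable,
    flank: int = PROMOTER_FLANK,
) -> pd.Series:
    """Enhancer-contact class per gene: P / distal_long / distal_short / none.

    ``annotated_peaks`` carries best_n per peak (repeats module);
    ``classified_loops`` is the consensus-union table (loops module). A
    GGAA-bearing peak (best_n >= 1) overlapping the promoter gives class P;
    otherwise loops from the gene's bait bins are followed to their
    other-end bins, and the longest repeat found among peak-bearing other
    ends decides distal_long (n > 4) vs distal_short (1 <= n <= 4).
    """
    promoters = promoter_intervals(genes, flank)
    peak_trees = _peak_tree(annotated_peaks[annotated_peaks["best_n"] >= 1])
    baits = gene_bait_bins(genes, bin_table, flank)
    bin_best_n = _bin_peak_best_n(annotated_peaks[annotated_peaks["best_n"] >= 1], bin_table)
    loops_by_bait: dict[int, list[int]] = {}
    for rec in classified_loops.itertuples(index=False):
        loops_by_bait.setdefault(int(rec.bait_bin), []).append(int(rec.oe_bin))
    classes = {}
    for rec in promoters.itertuples(index=False):
        tree = peak_trees.get(rec.chrom)
        if tree is not None and tree.overlap(rec.start, rec.end):
            classes[rec.gene_id] = "P"
            continue
        best_distal = 0
        for bait in baits[rec.gene_id]:
            for oe in loops_by_bait.get(bait, []):
                best_distal = max(best_distal, bin_best_n.get(oe, 0))
        if best_distal > 4:
            classes[rec.gene_id] = "distal_long"
        elif best_distal >= 1:
            classes[rec.gene_id] = "distal_short"
        else:
            classes[rec.gene_id] = "none"
    return pd.Series(classes, name="enhancer_class")


def gene_relevant_loops(
    gene_id: str,
    baits: dict[str, list[int]],
    classified_loops: pd.DataFrame,
    oe_filter: set[int] | None = None,
) -> pd.DataFrame:
    """Loops emanating from a gene's bait bins, optionally restricted by other end."""
    sel = classified_loops[classified_loops["bait_bin"].isin(baits.get(gene_id, []))]
    if oe_filter is not None:
        sel = sel[sel["oe_bin"].isin(oe_filter)]
    return sel


def contact_change_summary(
    loop_labels: pd.Series, delta_log2: pd.Series, deadband: float = DEADBAND
) -> str:
    """Summarize a gene's relevant loops into one contact-change label.

    All loops lost -> "lost"; all gained -> "gained"; otherwise the mean
    differential strength decides: below -deadband "down", above +deadband
    "up", within the dead-band "common". A gene with no relevant loop is an
    error (such genes are excluded upstream).
    """
    if len(loop_labels) == 0:
        raise ValueError("gene has no relevant loops")
    labels = set(loop_labels)
    if labels == {"lost"}:
        return "lost"
    if labels == {"gained"}:
        return "gained"
    mean_delta = float(np.mean(delta_log2))
    if mean_delta < -deadband:
        return "down"
    if mean_delta > deadband:
        return "up"
    return "common"


def contact_changes_for_genes(
    genes: pd.DataFrame,
    classified_loops: pd.DataFrame,
    delta_log2: pd.Series,
    bin_table: BinTable,
    flank: int = PROMOTER_FLANK,
    oe_filter: set[int] | None = None,
    deadband: float = DEADBAND,
) -> pd.Series:
    """Per-gene contact-change label; genes without relevant loops are omitted.

    ``delta_log2`` is indexed like ``classified_loops`` (one differential
    strength per loop row).
    """
    baits = gene_bait_bins(genes, bin_table, flank)
    out = {}
    for gene_id in genes["gene_id"]:
        sel = gene_relevant_loops(gene_id, baits, classified_loops, oe_filter)
        if len(sel) == 0:
            continue
        out[gene_id] = contact_change_summary(
            sel["label"], delta_log2.loc[sel.index], deadband
        )
    return pd.Series(out, name="contact_change")


def select_ctcf_cohesin_genes(
    genes: pd.DataFrame,
    classified_loops: pd.DataFrame,
    cohesin_peaks: pd.DataFrame,
    ctcf_peaks: pd.DataFrame,
    bin_table: BinTable,
    direct_targets: set[str],
    flank: int = PROMOTER_FLANK,
) -> set[str]:
    """Genes with cohesin/CTCF-anchored promoter loops, excluding EF targets.

    A qualifying gene is not an EWS::FLI1 direct target and has at least one
    promoter loop whose two anchor bins both overlap a cohesin peak, with a
    CTCF peak at one anchor or the other.
    """
    def bins_overlapping(peaks: pd.DataFrame) -> set[int]:
        hit: set[int] = set()
        trees = {
            chrom: IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
            for chrom, grp in peaks.groupby("chrom")
        }
        for rec in bin_table.bins.itertuples(index=False):
            tree = trees.get(rec.chrom)
            if tree is not None and tree.overlaps(rec.start, rec.end):
                hit.add(int(rec.bin_id))
        return hit

    cohesin_bins = bins_overlapping(cohesin_peaks)
    ctcf_bins = bins_overlapping(ctcf_peaks)
    baits = gene_bait_bins(genes, bin_table, flank)
    selected = set()
    for gene_id in genes["gene_id"]:
        if gene_id in direct_targets:
            continue
        sel = gene_relevant_loops(gene_id, baits, classified_loops)
        for rec in sel.itertuples(index=False):
            both_cohesin = rec.bait_bin in cohesin_bins and rec.oe_bin in cohesin_bins
            any_ctcf = rec.bait_bin in ctcf_bins or rec.oe_bin in ctcf_bins
            if both_cohesin and any_ctcf:
                selected.add(gene_id)
                break
    return selected


@dataclass
class GroupComparison:
    """Group summaries plus the rank-test p-value used for boxplot figures."""

    summaries: pd.DataFrame  # group, n, median, q1, q3
    test: str  # mannwhitney | kruskal
    statistic: float
    p_value: float


def expression_by_class(
    values: pd.Series, groups: pd.Series
) -> GroupComparison:
    """Median/quartile summaries per group with a rank-based comparison.

    Two groups are compared with the two-sided Mann-Whitney U test, three or
    more with Kruskal-Wallis. ``values`` is typically per-gene log2FC,
    ``groups`` the enhancer-class or contact-change label.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    arrays = [grp["value"].to_numpy() for _, grp in df.groupby("group")]
    names = [name for name, _ in df.groupby("group")]
    arrays = [a for a in arrays if len(a)]
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    rows = [
        (name, len(a), float(np.median(a)), float(np.quantile(a, 0.25)),
         float(np.quantile(a, 0.75)))
        for name, a in zip(names, arrays)
    ]
    summaries = pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison(summaries, "mannwhitney", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*arrays)
    return GroupComparison(summaries, "kruskal", float(res.statistic), float(res.pvalue))
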