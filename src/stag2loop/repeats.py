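"""GGAA microsatellite detection and peak annotation.

EWS::FLI1, the Ewing sarcoma fusion oncoprotein, binds GGAA motifs; chained
runs of the motif ("microsatellites") act as neoenhancers, and runs of more
than four motifs bind the oncoprotein much more strongly than shorter ones.
This module finds such runs in raw sequence, annotates ChIP-seq peaks with
the longest run they contain, and applies the standard peak quality filter
(blacklist exclusion plus a -log10 q-value floor).

A *run* chains consecutive, non-overlapping motif occurrences as long as the
gap between the end of one motif and the start of the next does not exceed
``max_gap`` (default 5 nt). Runs are scanned independently on the forward
strand (GGAA) and the reverse strand (TTCC on the forward sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

MOTIF_LEN = 4
_FORWARD = re.compile("GGAA")
_REVERSE = re.compile("TTCC")
_VALID_CHARS = frozenset("ACGTN")

#: runs with more than this many motifs are "long" (microsatellite class)
LONG_REPEAT_MIN_N = 5


@dataclass(frozen=True)
class RepeatRun:
    """A maximal chain of GGAA motifs on one strand.

    Coordinates are 0-based half-open on the forward sequence; ``n_motifs``
    is the number of chained motif copies (the *n* used to call a repeat
    short, 1 <= n <= 4, or long, n > 4).
    """

    chrom: str
    start: int
    end: int
    n_motifs: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start < MOTIF_LEN:
            raise ValueError(f"run shorter than one motif: {self}")
        if self.n_motifs == 1 and self.end - self.start != MOTIF_LEN:
            raise ValueError(f"single-motif run must span {MOTIF_LEN} bp: {self}")


@dataclass(frozen=True)
class PeakAnnotation:
    """A peak interval with the longest overlapping repeat run."""

    chrom: str
    start: int
    end: int
    best_n: int
    repeat_class: str  # none | short | long


def classify_repeat(n_motifs: int) -> str:
    """Map a motif count to the repeat-length class used throughout."""
    if n_motifs >= LONG_REPEAT_MIN_N:
        return "long"
    if n_motifs >= 1:
        return "short"
    return "none"


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def _chain_occurrences(
    starts: list[int], chrom: str, strand: str, max_gap: int
) -> list[RepeatRun]:
    """Greedy left-to-right chaining of motif start positions.

    All motifs have length 4 and cannot overlap themselves, so the greedy
    chaining of the sorted occurrence list is the unique maximal chaining.
    """
    runs: list[RepeatRun] = []
    if not starts:
        return runs
    run_start = starts[0]
    prev_end = starts[0] + MOTIF_LEN
    n = 1
    for s in starts[1:]:
        if s - prev_end <= max_gap:
            n += 1
        else:
            runs.append(RepeatRun(chrom, run_start, prev_end, n, strand))
            run_start = s
            n = 1
        prev_end = s + MOTIF_LEN
    runs.append(RepeatRun(chrom, run_start, prev_end, n, strand))
    return runs


def scan_runs(
    sequence: str,
    chrom: str = "seq",
    max_gap: int = 5,
    strand_mode: str = "both",
) -> list[RepeatRun]:
    """Find all maximal GGAA repeat runs in ``sequence``.

    Parameters
    ----------
    sequence : DNA string over A/C/G/T/N; N never matches.
    max_gap : maximum allowed distance (nt) between the end of one motif and
        the start of the next within a single run.
    strand_mode : "forward" scans GGAA only; "both" also scans TTCC and
        reports those runs with strand "-".
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    seq = _validate_sequence(sequence)
    runs = _chain_occurrences(
        [m.start() for m in _FORWARD.finditer(seq)], chrom, "+", max_gap
    )
    if strand_mode == "both":
        runs += _chain_occurrences(
            [m.start() for m in _REVERSE.finditer(seq)], chrom, "-", max_gap
        )
    return sorted(runs, key=lambda r: (r.start, r.strand))


def annotate_peaks(
    peaks: pd.DataFrame,
    genome: dict,
    max_gap: int = 5,
    strand_mode: str = "both",
) -> list[PeakAnnotation]:
    """Annotate each peak with the longest repeat run it overlaps.

    ``genome`` maps chromosome name to sequence (a plain dict or a
    ``pyfaidx.Fasta``). Overlap means >= 1 bp intersection between the
    peak and the run span; ``best_n`` is the maximum ``n_motifs`` over
    overlapping runs (over both strands when strand_mode="both"), 0 when
    none overlaps.
    """
    unknown = set(peaks["chrom"]) - set(str(k) for k in genome.keys())
    if unknown:
        bad = peaks[peaks["chrom"].isin(unknown)]
        raise ValueError(
            f"peaks on chromosomes absent from the genome: {bad.to_dict('records')}"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom in peaks["chrom"].unique():
        seq = str(genome[chrom][:]) if not isinstance(genome[chrom], str) else genome[chrom]
        tree = IntervalTree()
        for run in scan_runs(seq, chrom=chrom, max_gap=max_gap, strand_mode=strand_mode):
            tree.addi(run.start, run.end, run.n_motifs)
        trees[chrom] = tree
    out = []
    for rec in peaks.itertuples(index=False):
        hits = trees[rec.chrom].overlap(rec.start, rec.end)
        best_n = max((h.data for h in hits), default=0)
        out.append(
            PeakAnnotation(rec.chrom, rec.start, rec.end, best_n, classify_repeat(best_n))
        )
    return out


def annotations_to_frame(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    """Peak annotations as a BED-like DataFrame."""
    return pd.DataFrame(
        [(a.chrom, a.start, a.end, a.best_n, a.repeat_class) for a in annotations],
        columns=["chrom", "start", "end", "best_n", "repeat_class"],
    )


def filter_peaks(
    peaks: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    q_min: float = 5.0,
) -> pd.DataFrame:
    """Retain unique peaks with q >= q_min and no blacklist overlap.

    The ``q`` column is on the -log10 scale, as emitted by the peak caller;
    the default floor of 5 corresponds to q-value 1e-5. Peaks duplicated on
    (chrom, start, end) are collapsed to the first occurrence.
    """
    if "q" not in peaks.columns:
        raise ValueError("peak table lacks the required 'q' column (-log10 scale)")
    kept = peaks[peaks["q"] >= q_min].drop_duplicates(subset=["chrom", "start", "end"])
    if blacklist is not None and len(blacklist):
        trees = {
            chrom: IntervalTree.from_tuples(
                zip(grp["start"], grp["end"])
            )
            for chrom, grp in blacklist.groupby("chrom")
        }
        mask = [
            not (rec.chrom in trees and trees[rec.chrom].overlaps(rec.start, rec.end))
            for rec in kept.itertuples(index=False)
        ]
        kept = kept[mask]
    return kept.reset_index(drop=True)
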