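"""Loop-call filtering, consensus sets, and common/gained/lost classification.

Promoter Capture Hi-C loops are called per cell line — two STAG2-proficient
lines (Parental, WT clone) and two STAG2-knockout clones (KO1, KO2). Calls
passing the read and score thresholds are reduced to two consensus sets
(present in both proficient lines, or in both KO clones); loops in the union
are then classified by their 4-line presence pattern:

* called in >= 3 of 4 lines         -> common
* called only in the proficient pair -> lost (upon STAG2 loss)
* called only in the KO pair         -> gained

Any other pattern inside the union is left unclassified and excluded from
downstream contact/expression integration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import BinTable

CELL_LINES = ("P", "WT", "KO1", "KO2")
WT_LINES = ("P", "WT")
KO_LINES = ("KO1", "KO2")

#: default loop-length strata (bp): sub-cohesin, cohesin-range, upper, inter-TAD
DEFAULT_SIZE_BINS = ((0, 80_000), (80_000, 800_000), (800_000, 1_000_000),
                     (1_000_000, np.inf))


@dataclass(frozen=True)
class LoopCall:
    """One called interaction in one cell line."""

    bait_bin: int
    oe_bin: int
    n_reads: int
    score: float
    cell_line: str


def filter_calls(
    calls: pd.DataFrame, min_reads: int = 5, min_score: float = 3.0
) -> pd.DataFrame:
    """Keep calls with n_reads >= min_reads and score strictly > min_score."""
    required = {"bait_bin", "oe_bin", "n_reads", "score"}
    if not required.issubset(calls.columns):
        raise ValueError(f"call table missing columns: {required - set(calls.columns)}")
    kept = calls[(calls["n_reads"] >= min_reads) & (calls["score"] > min_score)]
    return kept.reset_index(drop=True)


def _identity_sets(calls_by_line: dict[str, pd.DataFrame]) -> dict[str, set]:
    return {
        line: set(map(tuple, df[["bait_bin", "oe_bin"]].itertuples(index=False)))
        for line, df in calls_by_line.items()
    }


def consensus_sets(calls_by_line: dict[str, pd.DataFrame]) -> tuple[set, set]:
    """Loops present in both proficient lines (WT set) / both KO clones (KO set).

    Loop identity is exact (bait_bin, oe_bin) equality on the shared bin
    grid. Input is a dict of *filtered* call tables keyed by cell line.
    """
    missing = set(CELL_LINES) - set(calls_by_line)
    if missing:
        raise ValueError(f"missing cell lines: {sorted(missing)}")
    ids = _identity_sets(calls_by_line)
    wt_set = ids["P"] & ids["WT"]
    ko_set = ids["KO1"] & ids["KO2"]
    return wt_set, ko_set


def classify_pattern(pattern: tuple[int, int, int, int]) -> str:
    """Label one presence pattern over (P, WT, KO1, KO2)."""
    if sum(pattern) >= 3:
        return "common"
    if pattern == (1, 1, 0, 0):
        return "lost"
    if pattern == (0, 0, 1, 1):
        return "gained"
    return "unclassified"


def classify_loops(
    calls_by_line: dict[str, pd.DataFrame], bin_table: BinTable | None = None
) -> pd.DataFrame:
    """Classify every loop in the consensus-set union by its presence pattern.

    Returns a table (bait_bin, oe_bin, P, WT, KO1, KO2, label[, length_bp])
    restricted to WT_set | KO_set. ``length_bp`` (anchor-midpoint distance)
    is included when a bin table is supplied.
    """
    wt_set, ko_set = consensus_sets(calls_by_line)
    union = sorted(wt_set | ko_set)
    ids = _identity_sets(calls_by_line)
    rows = []
    for bait, oe in union:
        pattern = tuple(int((bait, oe) in ids[line]) for line in CELL_LINES)
        rows.append((bait, oe, *pattern, classify_pattern(pattern)))
    out = pd.DataFrame(rows, columns=["bait_bin", "oe_bin", *CELL_LINES, "label"])
    if bin_table is not None and len(out):
        mid = bin_table.midpoints()
        out["length_bp"] = np.abs(
            mid[out["oe_bin"].to_numpy()] - mid[out["bait_bin"].to_numpy()]
        )
    elif bin_table is not None:
        out["length_bp"] = pd.Series(dtype=int)
    return out


def loop_lengths(loops: pd.DataFrame, bin_table: BinTable) -> np.ndarray:
    """Midpoint-to-midpoint anchor distance in bp for each loop row."""
    mid = bin_table.midpoints()
    return np.abs(mid[loops["oe_bin"].to_numpy()] - mid[loops["bait_bin"].to_numpy()])


def length_profile(
    loops: pd.DataFrame,
    bin_table: BinTable,
    size_bins=DEFAULT_SIZE_BINS,
    by: str | None = None,
) -> pd.DataFrame:
    """Histogram of loop lengths over size strata, optionally per group.

    ``size_bins`` are half-open (lo, hi] ranges in bp and must not overlap;
    ``by`` names a grouping column (e.g. "label" or a cell-line column).
    """
    edges = sorted(size_bins)
    for (lo1, hi1), (lo2, hi2) in itertools.pairwise(edges):
        if hi1 > lo2:
            raise ValueError("size bins must not overlap")
    labels = [f"{lo}-{hi}" for lo, hi in edges]
    groups = [("all", loops)] if by is None else list(loops.groupby(by))
    rows = []
    for name, grp in groups:
        lengths = loop_lengths(grp, bin_table) if len(grp) else np.array([])
        for (lo, hi), lab in zip(edges, labels):
            count = int(np.sum((lengths > lo) & (lengths <= hi)))
            rows.append((name, lab, lo, hi, count))
    return pd.DataFrame(rows, columns=["group", "stratum", "lo_bp", "hi_bp", "count"])
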