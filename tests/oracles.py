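"""Independent brute-force oracles used to check the implementations.

These deliberately re-derive results by the most literal route available
(position-by-position scans, dense matrix arithmetic) and share no code
with the package internals they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_runs(seq: str, motif: str, max_gap: int) -> list[tuple[int, int, int]]:
    """All maximal motif runs as (start, end, n) via position-wise scanning."""
    seq = seq.upper()
    k = len(motif)
    occ = []
    i = 0
    while i <= len(seq) - k:
        if seq[i : i + k] == motif:
            occ.append(i)
            i += k  # non-overlapping, left-to-right
        else:
            i += 1
    runs = []
    j = 0
    while j < len(occ):
        start = occ[j]
        n = 1
        end = start + k
        while j + 1 < len(occ) and occ[j + 1] - end <= max_gap:
            j += 1
            n += 1
            end = occ[j] + k
        runs.append((start, end, n))
        j += 1
    return runs


def classify_pattern_table() -> dict[tuple[int, int, int, int], str]:
    """Hand-derived rule table over all 16 presence patterns (P, WT, KO1, KO2)."""
    table = {}
    for p in range(2):
        for w in range(2):
            for k1 in range(2):
                for k2 in range(2):
                    pat = (p, w, k1, k2)
                    if p + w + k1 + k2 >= 3:
                        table[pat] = "common"
                    elif pat == (1, 1, 0, 0):
                        table[pat] = "lost"
                    elif pat == (0, 0, 1, 1):
                        table[pat] = "gained"
                    else:
                        table[pat] = "unclassified"
    return table


def dense_matrix(pixels, n: int) -> np.ndarray:
    """Dense symmetric matrix from canonical (bin1 <= bin2) raw pixels."""
    d = np.zeros((n, n))
    for b1, b2, c in pixels[["bin1_id", "bin2_id", "count"]].itertuples(index=False):
        d[b1, b2] += c
        if b1 != b2:
            d[b2, b1] += c
    return d


def dense_row_normalize(dense: np.ndarray, is_bait: np.ndarray) -> np.ndarray:
    """Bait rows divided by their row sum; non-bait rows zeroed."""
    out = np.zeros_like(dense)
    for r in np.flatnonzero(is_bait):
        s = dense[r].sum()
        if s > 0:
            out[r] = dense[r] / s
    return out


def dense_decay_normalize(
    rows: np.ndarray, is_bait: np.ndarray, chrom_of: np.ndarray
) -> np.ndarray:
    """O/E of a dense bait-row matrix: per-chromosome expected by distance.

    Expected at distance d is the mean of the bait-row values at that
    distance, zeros included over every valid (row, partner) position.
    """
    out = np.zeros_like(rows)
    for chrom in np.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        lo, hi = idx[0], idx[-1] + 1
        n = hi - lo
        baits = [r for r in np.flatnonzero(is_bait) if lo <= r < hi]
        if not baits:
            continue
        max_d = n - 1
        sums = np.zeros(max_d + 1)
        counts = np.zeros(max_d + 1)
        for r in baits:
            i = r - lo
            for d in range(0, max_d + 1):
                for j in sorted({i - d, i + d}):  # the diagonal counts once
                    if 0 <= j < n:
                        sums[d] += rows[r, lo + j]
                        counts[d] += 1
        expected = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        for r in baits:
            i = r - lo
            for j in range(n):
                d = abs(j - i)
                if expected[d] > 0:
                    out[r, lo + j] = rows[r, lo + j] / expected[d]
    return out
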