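"""Binned contact matrices for Promoter Capture Hi-C.

A :class:`ContactMatrix` holds sparse symmetric counts over a genome-wide
:class:`BinTable` (3-kb bins by default) in which a subset of bins is flagged
as capture baits (promoter fragments). Three operations mirror the analysis
that turns raw capture counts into comparable loop strengths:

* :func:`downsample_to_match` — equalize on-target (bait-touching) read
  totals across conditions by subsampling without replacement, so library
  depth does not masquerade as biology;
* :func:`row_normalize` — divide every bait row by its total, making rows
  comparable between baits;
* :func:`decay_normalize` — divide by the mean row-normalized value at the
  same genomic distance (computed over bait rows only, zeros included), the
  observed/expected (O/E) transform that removes the power-law distance
  decay of chromatin contacts.

Loop strength is the O/E value at a loop's (bait, other-end) pixel, and
differential strength the log2 ratio between conditions with a small
pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

RAW = "raw"
ROW = "row"
ROW_DECAY = "row+decay"


@dataclass(frozen=True)
class BinTable:
    """Genome tiling into fixed-size bins with a per-bin bait flag.

    ``bins`` columns: chrom, start, end, bin_id, is_bait. Bin ids are dense,
    sorted, and contiguous within each chromosome, so within a chromosome
    the genomic distance between two bins is ``|id1 - id2| * bin_size``.
    """

    bins: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        b = self.bins
        required = {"chrom", "start", "end", "bin_id", "is_bait"}
        if not required.issubset(b.columns):
            raise ValueError(f"bin table missing columns: {required - set(b.columns)}")
        ids = b["bin_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(b))):
            raise ValueError("bin_ids must be dense and sorted from 0")
        for _, grp in b.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError("bins must tile each chromosome without gaps/overlap")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def is_bait(self) -> np.ndarray:
        return self.bins["is_bait"].to_numpy(dtype=bool)

    @property
    def bait_ids(self) -> np.ndarray:
        return self.bins.loc[self.bins["is_bait"].astype(bool), "bin_id"].to_numpy()

    @property
    def chrom_of(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def chrom_ranges(self) -> dict[str, tuple[int, int]]:
        """Half-open bin_id range per chromosome."""
        out = {}
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            out[chrom] = (int(grp["bin_id"].iloc[0]), int(grp["bin_id"].iloc[-1]) + 1)
        return out

    def midpoints(self) -> np.ndarray:
        return ((self.bins["start"] + self.bins["end"]) // 2).to_numpy()

    def bin_of(self, chrom: str, pos: int) -> int:
        """bin_id of the bin containing genomic position ``pos``."""
        grp = self.bins[self.bins["chrom"] == chrom]
        if grp.empty:
            raise KeyError(f"unknown chromosome {chrom!r}")
        idx = grp.index[(grp["start"] <= pos) & (pos < grp["end"])]
        if len(idx) == 0:
            raise ValueError(f"position {chrom}:{pos} outside binned range")
        return int(grp.loc[idx[0], "bin_id"])

    def same_table(self, other: "BinTable") -> bool:
        return self.bin_size == other.bin_size and self.bins.equals(other.bins)


def make_bin_table(chrom_sizes: dict[str, int], bin_size: int,
                   bait_positions: dict[str, list[int]] | None = None) -> BinTable:
    """Tile chromosomes into bins; mark bins containing any bait position."""
    rows = []
    bin_id = 0
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size), bin_id, False))
            bin_id += 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id", "is_bait"])
    table = BinTable(bins=bins, bin_size=bin_size)
    if bait_positions:
        flags = bins["is_bait"].to_numpy().copy()
        for chrom, positions in bait_positions.items():
            for pos in positions:
                flags[table.bin_of(chrom, pos)] = True
        bins = bins.assign(is_bait=flags)
        table = BinTable(bins=bins, bin_size=bin_size)
    return table


@dataclass
class ContactMatrix:
    """Sparse binned contact matrix for one condition.

    In the ``raw`` state ``pixels`` has columns (bin1_id, bin2_id, count)
    with bin1_id <= bin2_id (canonical upper-triangle storage of a symmetric
    matrix). After normalization ``pixels`` has columns (row_id, col_id,
    value): one directed row per bait bin, with bait-bait pixels appearing
    in both rows.
    """

    bin_table: BinTable
    pixels: pd.DataFrame
    condition: str = ""
    normalized: str = RAW

    def __post_init__(self) -> None:
        value_col = "count" if self.normalized == RAW else "value"
        if self.normalized == RAW:
            cols = {"bin1_id", "bin2_id", "count"}
            if not cols.issubset(self.pixels.columns):
                raise ValueError(f"raw pixels need columns {cols}")
            if len(self.pixels) and np.any(
                self.pixels["bin1_id"].to_numpy() > self.pixels["bin2_id"].to_numpy()
            ):
                raise ValueError("raw pixels must satisfy bin1_id <= bin2_id")
        else:
            cols = {"row_id", "col_id", "value"}
            if not cols.issubset(self.pixels.columns):
                raise ValueError(f"normalized pixels need columns {cols}")
        if len(self.pixels) and (self.pixels[value_col] < 0).any():
            raise ValueError("negative contact values")
        id_cols = ["bin1_id", "bin2_id"] if self.normalized == RAW else ["row_id", "col_id"]
        ids = self.pixels[id_cols].to_numpy()
        if len(ids) and (ids.max() >= self.bin_table.n_bins or ids.min() < 0):
            raise ValueError("pixel bin ids outside the bin table")

    def on_target_total(self) -> float:
        """Total count over pixels touching at least one bait bin."""
        if self.normalized != RAW:
            raise ValueError("on-target totals are defined for raw matrices")
        mask = self._on_target_mask()
        return float(self.pixels.loc[mask, "count"].sum())

    def _on_target_mask(self) -> np.ndarray:
        is_bait = self.bin_table.is_bait
        return (
            is_bait[self.pixels["bin1_id"].to_numpy(dtype=np.int64)]
            | is_bait[self.pixels["bin2_id"].to_numpy(dtype=np.int64)]
        )

    def to_bait_rows(self) -> pd.DataFrame:
        """Directed (row_id, col_id, value) view over bait rows only."""
        if self.normalized != RAW:
            return self.pixels[["row_id", "col_id", "value"]]
        is_bait = self.bin_table.is_bait
        px = self.pixels
        b1 = px["bin1_id"].to_numpy()
        b2 = px["bin2_id"].to_numpy()
        cnt = px["count"].to_numpy(dtype=float)
        parts = []
        m1 = is_bait[b1]
        parts.append(pd.DataFrame({"row_id": b1[m1], "col_id": b2[m1], "value": cnt[m1]}))
        m2 = is_bait[b2] & (b1 != b2)
        parts.append(pd.DataFrame({"row_id": b2[m2], "col_id": b1[m2], "value": cnt[m2]}))
        return pd.concat(parts, ignore_index=True)


def merge_conditions(matrices: list[ContactMatrix], condition: str) -> ContactMatrix:
    """Pixel-wise sum of raw replicate matrices (e.g. P+WT, KO1+KO2)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    for m in matrices:
        if m.normalized != RAW:
            raise ValueError("only raw matrices can be merged")
        if not m.bin_table.same_table(matrices[0].bin_table):
            raise ValueError("bin tables differ between matrices")
    merged = (
        pd.concat([m.pixels for m in matrices], ignore_index=True)
        .groupby(["bin1_id", "bin2_id"], as_index=False)["count"]
        .sum()
    )
    return ContactMatrix(matrices[0].bin_table, merged, condition=condition)


def downsample_to_match(matrices: list[ContactMatrix], seed: int) -> list[ContactMatrix]:
    """Subsample every matrix so on-target totals are equal across inputs.

    On-target pixels (those touching >= 1 bait bin) are subsampled without
    replacement to exactly the minimum on-target total across the inputs
    (multivariate hypergeometric over pixel counts); off-target pixels are
    subsampled without replacement at the same global rate. Pixel support
    never grows.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to match")
    for m in matrices:
        if m.normalized != RAW:
            raise ValueError("downsampling applies to raw matrices")
        if not m.bin_table.same_table(matrices[0].bin_table):
            raise ValueError("bin tables differ between matrices")
    totals = [m.on_target_total() for m in matrices]
    target = int(min(totals))
    rng = np.random.default_rng(seed)
    out = []
    for m in matrices:
        mask = m._on_target_mask()
        counts_on = m.pixels.loc[mask, "count"].to_numpy(dtype=np.int64)
        counts_off = m.pixels.loc[~mask, "count"].to_numpy(dtype=np.int64)
        total_on = int(counts_on.sum())
        rate = target / total_on if total_on > 0 else 0.0
        new_on = (
            rng.multivariate_hypergeometric(counts_on, target)
            if counts_on.size
            else counts_on
        )
        n_off = int(round(rate * counts_off.sum()))
        new_off = (
            rng.multivariate_hypergeometric(counts_off, n_off)
            if counts_off.size
            else counts_off
        )
        px = m.pixels.copy()
        px.loc[mask, "count"] = new_on
        px.loc[~mask, "count"] = new_off
        px = px[px["count"] > 0].reset_index(drop=True)
        out.append(replace(m, pixels=px))
    return out


def row_normalize(m: ContactMatrix) -> ContactMatrix:
    """Divide each bait row by its total so positive rows sum to 1."""
    if m.normalized != RAW:
        raise ValueError(f"row_normalize expects a raw matrix, got {m.normalized!r}")
    rows = m.to_bait_rows()
    sums = rows.groupby("row_id")["value"].transform("sum")
    rows = rows.assign(value=np.where(sums > 0, rows["value"] / sums, 0.0))
    rows = rows[rows["value"] > 0].reset_index(drop=True)
    return ContactMatrix(m.bin_table, rows, condition=m.condition, normalized=ROW)


def _distance_position_counts(bt: BinTable, bait_rows: np.ndarray,
                              max_d: int) -> dict[str, np.ndarray]:
    """Number of valid (bait row, partner bin) pairs at each distance, per chrom.

    For a bait at within-chromosome index i on a chromosome of n bins, the
    partners at distance d are i-d and i+d when they fall inside [0, n);
    these positions all count in the expected-value denominator, whether or
    not a pixel was observed there (zeros included).
    """
    counts: dict[str, np.ndarray] = {}
    ranges = bt.chrom_ranges()
    for chrom, (lo, hi) in ranges.items():
        n = hi - lo
        on_chrom = bait_rows[(bait_rows >= lo) & (bait_rows < hi)] - lo
        if on_chrom.size == 0:
            continue
        c = np.zeros(max_d + 1, dtype=np.int64)
        d = np.arange(max_d + 1)
        for i in on_chrom:
            c += (i - d >= 0).astype(np.int64) + ((i + d <= n - 1) & (d > 0)).astype(np.int64)
        counts[chrom] = c
    return counts


def decay_normalize(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform of a row-normalized matrix.

    Expected at bin distance d is the mean row-normalized value at that
    distance over bait rows only, computed per chromosome with unobserved
    (zero) positions included in the mean. Inter-chromosomal pixels have no
    distance and are dropped.
    """
    if m.normalized != ROW:
        raise ValueError(f"decay_normalize expects a row-normalized matrix, got {m.normalized!r}")
    bt = m.bin_table
    bait_rows = bt.bait_ids
    if bait_rows.size == 0:
        raise ValueError("no bait rows in bin table")
    px = m.pixels
    chrom = bt.chrom_of
    same_chrom = chrom[px["row_id"].to_numpy()] == chrom[px["col_id"].to_numpy()]
    px = px[same_chrom].reset_index(drop=True)
    dist = np.abs(px["row_id"].to_numpy() - px["col_id"].to_numpy())
    pchrom = chrom[px["row_id"].to_numpy()]
    max_d = int(dist.max()) if len(px) else 0
    denom = _distance_position_counts(bt, bait_rows, max_d)
    oe = np.zeros(len(px))
    for ch in np.unique(pchrom):
        sel = pchrom == ch
        sums = np.bincount(dist[sel], weights=px.loc[sel, "value"].to_numpy(),
                           minlength=max_d + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.where(denom[ch] > 0, sums / np.maximum(denom[ch], 1), 0.0)
        e = expected[dist[sel]]
        oe[sel] = np.where(e > 0, px.loc[sel, "value"].to_numpy() / e, 0.0)
    out = px.assign(value=oe)
    out = out[out["value"] > 0].reset_index(drop=True)
    return ContactMatrix(bt, out, condition=m.condition, normalized=ROW_DECAY)


def normalize(m: ContactMatrix) -> ContactMatrix:
    """Convenience: row-normalize then decay-normalize a raw matrix."""
    return decay_normalize(row_normalize(m))


def loop_strength(m: ContactMatrix, bait_bin: int, oe_bin: int) -> float:
    """O/E value at a loop's (bait, other-end) pixel; 0 when absent."""
    if m.normalized != ROW_DECAY:
        raise ValueError("loop strength is read from an O/E (row+decay) matrix")
    n = m.bin_table.n_bins
    if not (0 <= bait_bin < n and 0 <= oe_bin < n):
        raise ValueError(f"loop anchor outside bin table: ({bait_bin}, {oe_bin})")
    hit = m.pixels[(m.pixels["row_id"] == bait_bin) & (m.pixels["col_id"] == oe_bin)]
    return float(hit["value"].iloc[0]) if len(hit) else 0.0


def loop_strengths(m: ContactMatrix, loops: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`loop_strength` over a (bait_bin, oe_bin) table."""
    if m.normalized != ROW_DECAY:
        raise ValueError("loop strength is read from an O/E (row+decay) matrix")
    idx = pd.MultiIndex.from_frame(m.pixels[["row_id", "col_id"]])
    lookup = pd.Series(m.pixels["value"].to_numpy(), index=idx)
    keys = pd.MultiIndex.from_frame(loops[["bait_bin", "oe_bin"]])
    return lookup.reindex(keys).fillna(0.0).to_numpy()


def differential_strength(
    s_ko: np.ndarray, s_wt: np.ndarray, pseudocount: float | None = None
) -> np.ndarray:
    """log2 KO/WT loop-strength change with a data-scaled pseudocount.

    By default the pseudocount is 10% of the median positive strength over
    both conditions; pass an explicit value (possibly 0) to override.
    """
    s_ko = np.asarray(s_ko, dtype=float)
    s_wt = np.asarray(s_wt, dtype=float)
    if pseudocount is None:
        positive = np.concatenate([s_ko[s_ko > 0], s_wt[s_wt > 0]])
        pseudocount = 0.1 * float(np.median(positive)) if positive.size else 0.1
    with np.errstate(divide="ignore"):
        return np.log2(s_ko + pseudocount) - np.log2(s_wt + pseudocount)
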