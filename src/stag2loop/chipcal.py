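"""Spike-in calibration of ChIP-seq signal.

Calibrated ChIP-seq adds a fixed fraction of chromatin from a second species
(mouse, here) to every sample before immunoprecipitation. Reads mapping to
the spike-in genome act as an internal standard: the occupancy ratio

    OR = (Wm * IPh) / (Wh * IPm)

with W = input (whole-cell extract) reads, IP = immunoprecipitated reads, and
h/m the target/spike-in genomes, rescales coverage tracks so that genuine
global occupancy changes between conditions are preserved instead of being
normalized away. Coverage profiles are first normalized by sequencing depth
(mean 1x over covered bins) and then multiplied by the OR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CalibCounts:
    """Read counts entering the occupancy ratio.

    wh/wm: input reads mapped to the target/spike-in genome;
    iph/ipm: IP reads mapped to the target/spike-in genome.
    """

    wh: int
    wm: int
    iph: int
    ipm: int

    def __post_init__(self) -> None:
        for name in ("wh", "wm", "iph", "ipm"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}={getattr(self, name)}")

    def swapped(self) -> "CalibCounts":
        """Counts with target and spike-in genomes exchanged."""
        return CalibCounts(wh=self.wm, wm=self.wh, iph=self.ipm, ipm=self.iph)


def occupancy_ratio(c: CalibCounts) -> float:
    """Spike-in occupancy ratio OR = (Wm * IPh) / (Wh * IPm)."""
    for name in ("wh", "ipm"):
        if getattr(c, name) == 0:
            raise ZeroDivisionError(f"occupancy ratio undefined: {name} is zero")
    return (c.wm * c.iph) / (c.wh * c.ipm)


def _as_signal_dict(signal) -> dict[str, np.ndarray]:
    if isinstance(signal, dict):
        return {k: np.asarray(v, dtype=float) for k, v in signal.items()}
    return {"_": np.asarray(signal, dtype=float)}


def calibrate_coverage(coverage, counts: CalibCounts):
    """Depth-normalize a coverage track and apply the occupancy ratio.

    ``coverage`` is a per-bin signal array, or a dict of arrays keyed by
    chromosome. Covered bins (value > 0) are rescaled to mean 1, removing
    sequencing depth, then every bin is multiplied by ``occupancy_ratio``.
    The output therefore has mean OR over covered bins; doubling the input
    coverage leaves it unchanged.
    """
    sig = _as_signal_dict(coverage)
    concat = np.concatenate([v for v in sig.values()]) if sig else np.array([])
    covered = concat[concat > 0]
    if covered.size == 0:
        raise ValueError("all-zero coverage cannot be calibrated")
    if np.any(concat < 0):
        raise ValueError("coverage must be non-negative")
    scale = occupancy_ratio(counts) / covered.mean()
    out = {k: v * scale for k, v in sig.items()}
    if not isinstance(coverage, dict):
        return out["_"]
    return out


def _peak_bin_range(start: int, end: int, bin_size: int) -> tuple[int, int]:
    return start // bin_size, -(-end // bin_size)  # ceil division


def peak_log2fc(
    signal_a,
    signal_b,
    peaks: pd.DataFrame,
    bin_size: int,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-peak log2 fold change of calibrated signal A over B.

    Both signals must live on the same bin grid. For each peak the mean
    calibrated signal over the bins overlapping the peak span is computed in
    each condition and log2((meanA + pc) / (meanB + pc)) reported. The
    pseudocount (on the calibrated scale) guards empty peaks, which come out
    at exactly 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = _as_signal_dict(signal_a)
    b = _as_signal_dict(signal_b)
    if set(a) != set(b) or any(a[k].shape != b[k].shape for k in a):
        raise ValueError("signals are on different bin grids")
    single = not isinstance(signal_a, dict)
    rows = []
    for rec in peaks.itertuples(index=False):
        chrom = "_" if single else rec.chrom
        if chrom not in a:
            raise ValueError(f"peak chromosome {chrom!r} absent from signal")
        lo, hi = _peak_bin_range(rec.start, rec.end, bin_size)
        hi = min(hi, a[chrom].size)
        mean_a = a[chrom][lo:hi].mean() if hi > lo else 0.0
        mean_b = b[chrom][lo:hi].mean() if hi > lo else 0.0
        lfc = float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))
        rows.append((getattr(rec, "chrom", "_"), rec.start, rec.end, mean_a, mean_b, lfc))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean_a", "mean_b", "log2fc"]
    )
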