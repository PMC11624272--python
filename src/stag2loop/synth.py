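"""Synthetic data with planted ground truth for every pipeline stage.

Each generator emits one class of input the pipeline consumes — genomes with
planted GGAA repeat runs, spike-in read counts with a known occupancy ratio,
power-law-decaying contact matrices with planted condition-specific loops,
ChiCAGO-style loop-call tables, and expression cohorts in which a planted
signature of known direction and effect is tied to survival through a
proportional-hazards model. :func:`generate_study` assembles all of them
into one internally consistent study (genome, peaks, bins, loops, matrices,
contrasts, cohort) so the full pipeline can be exercised offline with the
planted truth as the oracle.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .chipcal import CalibCounts
from .contacts import BinTable, ContactMatrix, make_bin_table
from .loops import CELL_LINES, KO_LINES, WT_LINES

MOTIF = "GGAA"
MOTIF_RC = "TTCC"
_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Planted ground truth shared by the generators.

    planted_runs: (chrom, start, end, n_motifs, strand) tuples;
    planted_loops: :class:`PlantedLoop` records; signature_genes:
    (gene_id, direction, effect) tuples; patient_labels: sample -> group.
    """

    planted_runs: list = field(default_factory=list)
    planted_peaks: list = field(default_factory=list)
    planted_loops: list = field(default_factory=list)
    signature_genes: list = field(default_factory=list)
    patient_labels: dict = field(default_factory=dict)
    hazard_ratio: float | None = None


@dataclass(frozen=True)
class PlantedLoop:
    """A planted interaction with per-condition enrichment folds (>= 1)."""

    bait_bin: int
    oe_bin: int
    fold: dict  # condition -> fold; 1.0 means indistinguishable from decay

    def present(self, condition: str) -> bool:
        return self.fold.get(condition, 1.0) > 1.0

    def lines(self) -> dict:
        """Per-cell-line presence, expanding WT -> (P, WT) and KO -> (KO1, KO2)."""
        out = {}
        for line in WT_LINES:
            out[line] = self.present("WT")
        for line in KO_LINES:
            out[line] = self.present("KO")
        return out


# ---------------------------------------------------------------------------
# genome with planted GGAA runs


def _run_sequence(n_motifs: int, gap: int) -> str:
    return MOTIF + ("T" * gap + MOTIF) * (n_motifs - 1)


def _patch_background(seq: np.ndarray, keep_spans: list[tuple[int, int]],
                      rng: np.random.Generator) -> np.ndarray:
    """Destroy every GGAA/TTCC occurrence outside the planted run spans."""
    keep = np.zeros(len(seq), dtype=bool)
    for s, e in keep_spans:
        keep[s:e] = True
    text = "".join(seq)
    for _ in range(200):
        bad = []
        for motif in (MOTIF, MOTIF_RC):
            start = text.find(motif)
            while start != -1:
                if not keep[start : start + 4].all():
                    bad.append(start)
                start = text.find(motif, start + 1)
        if not bad:
            return np.array(list(text))
        arr = np.array(list(text))
        for start in bad:
            pos = start + 2
            assert not keep[pos], "patch position inside a planted run"
            current = arr[pos]
            choices = [b for b in "ACGT" if b != current]
            arr[pos] = rng.choice(choices)
        text = "".join(arr)
    raise RuntimeError("failed to clear background motifs")


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    run_spec: list[tuple[int, int]],
    bg_gc: float = 0.4,
    seed: int = 0,
    margin: int = 50,
) -> tuple[dict[str, str], SimTruth]:
    """Random genome with planted GGAA runs at recorded coordinates.

    ``run_spec`` lists (n_motifs, gap) pairs; gap is the spacing (nt,
    T-filled) between consecutive motifs within the run. Runs are placed
    round-robin across chromosomes at evenly spaced slots, and the
    background is guaranteed free of GGAA/TTCC occurrences, so the planted
    runs are exactly what a scanner should report (on the forward strand).
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    probs = [(1 - bg_gc) / 2, bg_gc / 2, bg_gc / 2, (1 - bg_gc) / 2]
    seqs = {c: rng.choice(_BASES, size=chrom_len, p=probs) for c in chroms}
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth = SimTruth()
    assignments: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i, (n_motifs, gap) in enumerate(run_spec):
        if n_motifs < 1 or gap < 0:
            raise ValueError(f"invalid run spec {(n_motifs, gap)}")
        assignments[chroms[i % n_chrom]].append((n_motifs, gap))
    for chrom in chroms:
        specs = assignments[chrom]
        if not specs:
            continue
        slot = (chrom_len - 2 * margin) // len(specs)
        for j, (n_motifs, gap) in enumerate(specs):
            run = _run_sequence(n_motifs, gap)
            start = margin + j * slot
            end = start + len(run)
            if end > chrom_len - margin or len(run) > slot - margin:
                raise ValueError(
                    f"run (n={n_motifs}, gap={gap}) does not fit on {chrom}: "
                    f"needs {len(run)} bp in a {slot} bp slot"
                )
            seqs[chrom][start:end] = list(run)
            per_chrom[chrom].append((start, end))
            truth.planted_runs.append((chrom, start, end, n_motifs, "+"))
    genome = {}
    for chrom in chroms:
        patched = _patch_background(seqs[chrom], per_chrom[chrom], rng)
        genome[chrom] = "".join(patched)
    return genome, truth


# ---------------------------------------------------------------------------
# spike-in calibrated ChIP counts


def generate_chip_counts(
    truth: SimTruth | None,
    or_true,
    depth: int,
    seed: int = 0,
    spike_frac: float = 0.05,
    ip_eff: float = 0.1,
) -> dict:
    """Read counts whose occupancy-ratio estimate recovers ``or_true``.

    Emulates a calibrated ChIP experiment in which ``spike_frac`` of the
    chromatin is spike-in: input reads split between target and spike-in
    genomes in proportion to chromatin amounts, IP reads in proportion to
    (true occupancy x chromatin), all Poisson at the stated ``depth``.
    ``or_true`` may be a single value or a dict per condition. Returns per
    condition a :class:`~stag2loop.chipcal.CalibCounts`, plus per-peak IP
    coverage when the truth carries planted peaks.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    conditions = or_true if isinstance(or_true, dict) else {"cond": float(or_true)}
    out = {}
    for cond, or_t in conditions.items():
        if or_t <= 0:
            raise ValueError(f"or_true must be > 0, got {or_t} for {cond}")
        counts = CalibCounts(
            wh=int(rng.poisson(depth)),
            wm=int(rng.poisson(spike_frac * depth)),
            iph=int(rng.poisson(or_t * ip_eff * depth)),
            ipm=int(rng.poisson(spike_frac * ip_eff * depth)),
        )
        peak_cov = None
        if truth is not None and truth.planted_peaks:
            lam = np.array([occ.get(cond, 1.0) for _, _, occ in truth.planted_peaks])
            peak_cov = rng.poisson(100.0 * lam).astype(float)
        out[cond] = {"counts": counts, "peak_coverage": peak_cov}
    if not isinstance(or_true, dict):
        return out["cond"]
    return out


# ---------------------------------------------------------------------------
# contact matrices with power-law decay and planted loops


def generate_contact_matrices(
    bins: BinTable,
    decay_exp: float,
    planted_loops: list[PlantedLoop],
    noise: float = 0.0,
    seed: int = 0,
    base_count: float = 600.0,
    max_dist_bins: int = 200,
    conditions: tuple[str, ...] = ("WT", "KO"),
) -> dict[str, ContactMatrix]:
    """Raw contact matrices with expected count ~ distance^(-decay_exp).

    Every intra-chromosomal bin pair at 1 <= d <= max_dist_bins receives an
    expected count base_count * d**(-decay_exp); planted loop pixels are
    multiplied by their per-condition fold. With ``noise`` > 0 counts are
    Poisson draws around the expectation, otherwise the exact (float)
    expectations are returned — in that case a matrix with no planted loops
    has observed/expected exactly 1 wherever bait rows share a full distance
    profile (baits at least max_dist_bins from chromosome ends).
    """
    if decay_exp <= 0:
        raise ValueError("decay_exp must be > 0")
    n = bins.n_bins
    for loop in planted_loops:
        if not (0 <= loop.bait_bin < n and 0 <= loop.oe_bin < n):
            raise ValueError(f"planted loop anchor outside bin range: {loop}")
        if any(f < 1 for f in loop.fold.values()):
            raise ValueError(f"loop fold must be >= 1: {loop}")
    rng = np.random.default_rng(seed)
    b1_parts, b2_parts, d_parts = [], [], []
    for chrom, (lo, hi) in bins.chrom_ranges().items():
        size = hi - lo
        for d in range(1, min(max_dist_bins, size - 1) + 1):
            i = np.arange(lo, hi - d)
            b1_parts.append(i)
            b2_parts.append(i + d)
            d_parts.append(np.full(i.size, d))
    b1 = np.concatenate(b1_parts)
    b2 = np.concatenate(b2_parts)
    dist = np.concatenate(d_parts)
    base = base_count * dist.astype(float) ** (-decay_exp)
    key = b1.astype(np.int64) * n + b2
    loop_index = {
        (min(l.bait_bin, l.oe_bin), max(l.bait_bin, l.oe_bin)): l
        for l in planted_loops
    }
    out = {}
    for cond in conditions:
        expected = base.copy()
        for (lo_bin, hi_bin), loop in loop_index.items():
            hit = np.flatnonzero(key == np.int64(lo_bin) * n + hi_bin)
            if hit.size == 0:
                raise ValueError(
                    f"planted loop ({lo_bin}, {hi_bin}) beyond max_dist_bins"
                )
            expected[hit] *= loop.fold.get(cond, 1.0)
        counts = rng.poisson(expected).astype(float) if noise > 0 else expected
        px = pd.DataFrame({"bin1_id": b1, "bin2_id": b2, "count": counts})
        px = px[px["count"] > 0].reset_index(drop=True)
        out[cond] = ContactMatrix(bins, px, condition=cond)
    return out


# ---------------------------------------------------------------------------
# loop-call tables


def generate_loop_calls(
    planted_loops: list[PlantedLoop],
    detect_prob: float = 1.0,
    seed: int = 0,
    read_dist=None,
    score_dist=None,
    fail_frac: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Per-cell-line call tables emulating a loop caller's filtered output.

    Each planted loop, in every cell line where it is present, is emitted
    with probability ``detect_prob``. Read counts default to a shifted
    negative binomial (always >= 5) and scores to a shifted gamma (always
    > 3); with ``fail_frac`` > 0 that fraction of emitted calls instead
    receives sub-threshold reads or a score at exactly the threshold, to
    exercise downstream filtering.
    """
    if not 0 <= detect_prob <= 1:
        raise ValueError("detect_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if read_dist is None:
        read_dist = lambda r, size: 5 + r.negative_binomial(2, 0.3, size)
    if score_dist is None:
        score_dist = lambda r, size: 3.0 + r.gamma(2.0, 1.0, size)
    tables = {line: [] for line in CELL_LINES}
    for loop in planted_loops:
        for line, present in loop.lines().items():
            if present and rng.random() < detect_prob:
                tables[line].append((loop.bait_bin, loop.oe_bin))
    out = {}
    for line in CELL_LINES:
        pairs = tables[line]
        k = len(pairs)
        reads = read_dist(rng, k).astype(int) if k else np.array([], dtype=int)
        scores = np.asarray(score_dist(rng, k), dtype=float) if k else np.array([])
        if k and fail_frac > 0:
            fail = rng.random(k) < fail_frac
            mode = rng.random(k) < 0.5
            reads = np.where(fail & mode, rng.integers(0, 5, k), reads)
            scores = np.where(fail & ~mode, 3.0, scores)
        out[line] = pd.DataFrame(
            {
                "bait_bin": [p[0] for p in pairs],
                "oe_bin": [p[1] for p in pairs],
                "n_reads": reads,
                "score": scores,
            }
        )
    return out


# ---------------------------------------------------------------------------
# expression cohort tied to survival


def make_signature(n_up: int, n_down: int, prefix: str = "SIG") -> pd.DataFrame:
    """A directed signature gene list for cohort simulation."""
    genes = [f"{prefix}_UP{i:03d}" for i in range(n_up)] + [
        f"{prefix}_DN{i:03d}" for i in range(n_down)
    ]
    return pd.DataFrame(
        {"gene_id": genes, "direction": ["up"] * n_up + ["down"] * n_down}
    )


def _censor_horizon(mean_rate: float, censor_rate: float) -> float:
    """Uniform-censoring horizon giving the requested censored fraction.

    With event times Exp(rate) and censoring Uniform(0, Tmax), the censored
    fraction is (1 - exp(-rate*Tmax)) / (rate*Tmax); solve for Tmax.
    """
    def frac(tmax):
        x = mean_rate * tmax
        return (1 - np.exp(-x)) / x - censor_rate

    return brentq(frac, 1e-9 / mean_rate, 1e9 / mean_rate)


def generate_cohort(
    n_patients: int,
    n_genes: int,
    signature: pd.DataFrame,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    hr: float = 3.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    frac_like: float = 0.5,
    baseline_rate: float = 0.01,
):
    """Expression cohort with a planted signature tied to survival.

    Signature-like patients have every up-regulated signature gene shifted
    by +effect and every down-regulated gene by -effect relative to the
    signature-different baseline, plus N(0, noise_sd) noise on all genes.
    Survival is exponential with baseline hazard ``baseline_rate`` per day,
    multiplied by ``hr`` for signature-like patients; censoring is uniform
    over a follow-up horizon chosen to censor ``censor_rate`` of patients
    in expectation.

    Returns (expression genes x samples, survival table, true labels).
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if n_genes < len(signature):
        raise ValueError(
            f"n_genes={n_genes} smaller than signature size {len(signature)}"
        )
    rng = np.random.default_rng(seed)
    sig_ids = list(signature["gene_id"])
    other = [f"BG{i:05d}" for i in range(n_genes - len(sig_ids))]
    gene_ids = sig_ids + other
    samples = [f"S{i:04d}" for i in range(n_patients)]
    n_like = int(round(frac_like * n_patients))
    like = np.zeros(n_patients, dtype=bool)
    like[rng.permutation(n_patients)[:n_like]] = True
    base = rng.normal(6.0, 1.0, size=n_genes)
    x = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_patients))
    direction = signature.set_index("gene_id")["direction"]
    for gi, gene in enumerate(sig_ids):
        shift = effect if direction[gene] == "up" else -effect
        x[gi, like] += shift
    rates = np.where(like, baseline_rate * hr, baseline_rate)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        tmax = _censor_horizon(float(rates.mean()), censor_rate)
        t_cens = rng.uniform(0.0, tmax, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    expression = pd.DataFrame(x, index=gene_ids, columns=samples)
    survival = pd.DataFrame(
        {"sample_id": samples, "time_days": time, "event": event}
    )
    labels = pd.Series(
        np.where(like, "signature-like", "signature-different"),
        index=samples,
        name="label",
    )
    return expression, survival, labels
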