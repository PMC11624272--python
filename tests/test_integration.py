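"""Gene enhancer classes, contact-change labels, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from stag2loop.contacts import BinTable, make_bin_table
from stag2loop.integration import (
    assign_enhancer_class,
    contact_change_summary,
    contact_changes_for_genes,
    expression_by_class,
    gene_bait_bins,
    promoter_intervals,
    select_ctcf_cohesin_genes,
    select_direct_targets,
)

BIN = 3000


def bait_table(n_bins, bait_bins):
    bt = make_bin_table({"chr1": n_bins * BIN}, BIN)
    flags = np.zeros(n_bins, dtype=bool)
    flags[list(bait_bins)] = True
    return BinTable(bins=bt.bins.assign(is_bait=flags), bin_size=BIN)


def gene_at(gene_id, tss_bin):
    return (gene_id, "chr1", tss_bin * BIN + 1500, "+")


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def peak_at(bin_id, best_n):
    cls = "long" if best_n > 4 else ("short" if best_n else "none")
    return ("chr1", bin_id * BIN + 1100, bin_id * BIN + 1500, best_n, cls)


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "best_n", "repeat_class"])


def loops_frame(rows):
    return pd.DataFrame(rows, columns=["bait_bin", "oe_bin", "label"])


class TestDirectTargets:
    def test_strict_boundary(self):
        contrast = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [0.5, 0.51, -0.6]}
        )
        assert select_direct_targets(contrast) == {"b", "c"}

    def test_empty(self):
        assert select_direct_targets(pd.DataFrame({"gene_id": [], "log2fc": []})) == set()


class TestEnhancerClass:
    def test_promoter_peak_gives_p(self):
        bt = bait_table(100, [10])
        genes = genes_frame([gene_at("g", 10)])
        cls = assign_enhancer_class(genes, peaks_frame([peak_at(10, 2)]),
                                    loops_frame([]), bt)
        assert cls["g"] == "P"

    def test_precedence_long_over_short(self):
        """A gene looped to both an n=6 and an n=2 peak is distal_long."""
        bt = bait_table(100, [10])
        genes = genes_frame([gene_at("g", 10)])
        peaks = peaks_frame([peak_at(40, 6), peak_at(60, 2)])
        loops = loops_frame([(10, 40, "common"), (10, 60, "common")])
        cls = assign_enhancer_class(genes, peaks, loops, bt)
        assert cls["g"] == "distal_long"

    def test_p_precedes_distal(self):
        bt = bait_table(100, [10])
        genes = genes_frame([gene_at("g", 10)])
        peaks = peaks_frame([peak_at(10, 1), peak_at(40, 6)])
        loops = loops_frame([(10, 40, "common")])
        cls = assign_enhancer_class(genes, peaks, loops, bt)
        assert cls["g"] == "P"

    def test_no_peaks_anywhere_gives_none(self):
        bt = bait_table(100, [10])
        genes = genes_frame([gene_at("g", 10)])
        cls = assign_enhancer_class(genes, peaks_frame([]), loops_frame([]), bt)
        assert cls["g"] == "none"

    def test_study_truth_recovered(self, noiseless_study):
        from stag2loop.loops import classify_loops, filter_calls
        from stag2loop.repeats import annotate_peaks, annotations_to_frame, filter_peaks

        s = noiseless_study
        kept = filter_peaks(s.peaks, s.blacklist)
        annotated = annotations_to_frame(annotate_peaks(kept, s.genome))
        calls = {k: filter_calls(v) for k, v in s.loop_calls.items()}
        classified = classify_loops(calls, s.bin_table)
        cls = assign_enhancer_class(s.genes, annotated, classified, s.bin_table)
        assert cls.to_dict() == s.truth["gene_classes"]


class TestContactChange:
    def test_all_lost(self):
        assert contact_change_summary(pd.Series(["lost", "lost"]),
                                      pd.Series([-2.0, -1.0])) == "lost"

    def test_all_gained(self):
        assert contact_change_summary(pd.Series(["gained"]), pd.Series([2.0])) == "gained"

    def test_zero_mean_within_deadband(self):
        assert contact_change_summary(pd.Series(["common", "common"]),
                                      pd.Series([0.1, -0.1])) == "common"

    def test_mixed_loops_down(self):
        """One lost, one unchanged, mean below the dead-band: down."""
        labels = pd.Series(["lost", "common"])
        delta = pd.Series([-2.0, 0.0])  # mean -1.0 < -0.25
        assert contact_change_summary(labels, delta) == "down"

    def test_up_beyond_deadband(self):
        assert contact_change_summary(pd.Series(["common"]), pd.Series([0.3])) == "up"

    def test_no_loops_fails(self):
        with pytest.raises(ValueError, match="no relevant"):
            contact_change_summary(pd.Series([], dtype=object), pd.Series([], dtype=float))

    def test_genes_without_loops_omitted(self):
        bt = bait_table(100, [10, 20])
        genes = genes_frame([gene_at("g1", 10), gene_at("g2", 20)])
        loops = loops_frame([(10, 40, "common")])
        out = contact_changes_for_genes(genes, loops, pd.Series([0.0]), bt)
        assert list(out.index) == ["g1"]


class TestCtcfCohesinSelection:
    def _setup(self):
        bt = bait_table(200, [10, 20, 30])
        genes = genes_frame([gene_at("g1", 10), gene_at("g2", 20), gene_at("g3", 30)])
        loops = loops_frame([(10, 50, "common"), (20, 60, "common"), (30, 70, "common")])
        return bt, genes, loops

    def _bed(self, bins):
        return pd.DataFrame(
            [("chr1", b * BIN + 500, b * BIN + 2500) for b in bins],
            columns=["chrom", "start", "end"],
        )

    def test_compliant_gene_selected(self):
        bt, genes, loops = self._setup()
        out = select_ctcf_cohesin_genes(
            genes, loops, self._bed([10, 50]), self._bed([50]), bt, set()
        )
        assert out == {"g1"}

    def test_cohesin_one_anchor_only_excluded(self):
        bt, genes, loops = self._setup()
        out = select_ctcf_cohesin_genes(
            genes, loops, self._bed([10]), self._bed([10, 50]), bt, set()
        )
        assert out == set()

    def test_direct_targets_excluded(self):
        bt, genes, loops = self._setup()
        out = select_ctcf_cohesin_genes(
            genes, loops, self._bed([10, 50]), self._bed([50]), bt, {"g1"}
        )
        assert out == set()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n_genes = 60
        # spaced so each promoter (TSS +/- 2 kb) touches exactly one bait bin
        bait_bins = list(range(10, 10 + 3 * n_genes, 3))
        bt = bait_table(400, bait_bins)
        genes = genes_frame([gene_at(f"g{i}", b) for i, b in enumerate(bait_bins)])
        loops = loops_frame(
            [(b, int(rng.integers(100, 390)), "common") for b in bait_bins
             for _ in range(rng.integers(0, 3))]
        )
        cohesin_bins = set(rng.choice(400, size=150, replace=False).tolist())
        ctcf_bins = set(rng.choice(400, size=80, replace=False).tolist())
        direct = {f"g{i}" for i in rng.choice(n_genes, size=10, replace=False)}
        got = select_ctcf_cohesin_genes(
            genes, loops, self._bed(sorted(cohesin_bins)),
            self._bed(sorted(ctcf_bins)), bt, direct,
        )
        expected = set()
        for i, b in enumerate(bait_bins):
            gid = f"g{i}"
            if gid in direct:
                continue
            for _, row in loops[loops["bait_bin"] == b].iterrows():
                ok_cohesin = row["bait_bin"] in cohesin_bins and row["oe_bin"] in cohesin_bins
                ok_ctcf = row["bait_bin"] in ctcf_bins or row["oe_bin"] in ctcf_bins
                if ok_cohesin and ok_ctcf:
                    expected.add(gid)
        assert got == expected


class TestExpressionByClass:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=300)
        groups = pd.Series(["a", "b", "c"] * 100)
        res = expression_by_class(pd.Series(v), groups)
        assert res.test == "kruskal" and res.p_value > 0.2

    def test_two_groups_use_mannwhitney(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        v = pd.Series(rng.normal(size=100))
        g = pd.Series(["a"] * 50 + ["b"] * 50)
        res = expression_by_class(v, g)
        ref = stats.mannwhitneyu(v[:50], v[50:], alternative="two-sided")
        assert res.test == "mannwhitney"
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_planted_downshift_detected(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 100), rng.normal(-1.0, 1, 100),
                                 rng.normal(0, 1, 100)])
        groups = ["P"] * 100 + ["distal_long"] * 100 + ["distal_short"] * 100
        res = expression_by_class(pd.Series(values), pd.Series(groups))
        medians = res.summaries.set_index("group")["median"]
        assert medians["distal_long"] < medians["P"]
        assert res.p_value < 0.01

    def test_single_group_fails(self):
        with pytest.raises(ValueError, match="two"):
            expression_by_class(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


def test_promoter_window_and_baits():
    bt = bait_table(100, [10])
    genes = genes_frame([gene_at("g", 10)])
    prom = promoter_intervals(genes)
    assert prom.loc[0, "start"] == 10 * BIN + 1500 - 2000
    assert prom.loc[0, "end"] == 10 * BIN + 1500 + 2000
    assert gene_bait_bins(genes, bt) == {"g": [10]}
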