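"""Signature derivation, centroid-initialized k-means, PCA, survival."""

import numpy as np
import pandas as pd
import pytest

from stag2loop.signature import (
    SIGNATURE_DIFFERENT,
    SIGNATURE_LIKE,
    build_models,
    classify_cohort,
    flag_wtstar,
    intersect_degs,
    pca_project,
    survival_compare,
)
from stag2loop.synth import generate_cohort, make_signature


def _contrast(gene_ids, log2fc, fdr):
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "fdr": fdr})


class TestIntersectDegs:
    def test_counting_oracle(self):
        """50 concordant + 20 discordant significant genes yield exactly 50."""
        genes = [f"g{i}" for i in range(90)]
        lfc_a = [1.0] * 50 + [1.0] * 20 + [1.0] * 20
        lfc_b = [0.5] * 50 + [-0.5] * 20 + [0.5] * 20
        fdr_a = [0.01] * 70 + [0.5] * 20  # last 20 not significant in A
        out = intersect_degs(
            _contrast(genes, lfc_a, fdr_a), _contrast(genes, lfc_b, [0.01] * 90)
        )
        assert len(out) == 50
        assert set(out["direction"]) == {"up"}

    def test_discordant_excluded(self):
        out = intersect_degs(
            _contrast(["g"], [1.0], [0.01]), _contrast(["g"], [-1.0], [0.01])
        )
        assert len(out) == 0

    def test_fdr_boundary_strict(self):
        out = intersect_degs(
            _contrast(["g"], [1.0], [0.05]), _contrast(["g"], [1.0], [0.01])
        )
        assert len(out) == 0

    def test_directions_carried(self):
        out = intersect_degs(
            _contrast(["a", "b"], [1.0, -2.0], [0.01, 0.01]),
            _contrast(["a", "b"], [0.5, -0.1], [0.01, 0.01]),
        )
        assert out.set_index("gene_id")["direction"].to_dict() == {
            "a": "up", "b": "down"
        }


class TestBuildModels:
    def test_two_sample_example(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [5.0]}, index=["g"])
        sig = pd.DataFrame({"gene_id": ["g"], "direction": ["up"]})
        model = build_models(expr, sig)
        assert model.ko_centroid["g"] == 5.0
        assert model.wt_centroid["g"] == 1.0

    def test_all_down_signature_mirrors(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [5.0, 8.0]}, index=["g1", "g2"]
        )
        sig = pd.DataFrame({"gene_id": ["g1", "g2"], "direction": ["down", "down"]})
        model = build_models(expr, sig)
        assert model.ko_centroid.tolist() == [1.0, 2.0]  # per-gene minima
        assert model.wt_centroid.tolist() == [5.0, 8.0]

    def test_constant_gene_contributes_nothing(self):
        expr = pd.DataFrame({"s1": [3.0], "s2": [3.0]}, index=["g"])
        sig = pd.DataFrame({"gene_id": ["g"], "direction": ["up"]})
        model = build_models(expr, sig)
        assert model.ko_centroid["g"] == model.wt_centroid["g"]

    def test_missing_genes_dropped_with_warning(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        sig = pd.DataFrame({"gene_id": ["g", "absent"], "direction": ["up", "up"]})
        with pytest.warns(UserWarning, match="1 signature genes absent"):
            model = build_models(expr, sig)
        assert model.gene_ids == ["g"]

    def test_zero_overlap_fails(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["g"])
        sig = pd.DataFrame({"gene_id": ["other"], "direction": ["up"]})
        with pytest.raises(ValueError, match="no signature genes"):
            build_models(expr, sig)


class TestClassifyCohort:
    sig = make_signature(4, 4)

    def _cohort(self, noise_sd, n=200, seed=0):
        expr, _, labels = generate_cohort(
            n, 30, self.sig, effect=2.0, noise_sd=noise_sd, seed=seed
        )
        return expr, labels

    def test_noiseless_recovery_is_exact(self):
        expr, truth = self._cohort(0.0)
        model = build_models(expr, self.sig)
        labels = classify_cohort(expr, model)
        assert (labels == truth).all()

    def test_accuracy_at_noise_equal_effect(self):
        expr, truth = self._cohort(2.0, n=200, seed=11)
        model = build_models(expr, self.sig)
        labels = classify_cohort(expr, model)
        assert (labels == truth).mean() >= 0.9

    def test_single_sample_assigned_to_nearer_centroid(self):
        expr, _ = self._cohort(0.0, n=40)
        model = build_models(expr, self.sig)
        one = expr.iloc[:, [0]]
        (label,) = classify_cohort(one, model)
        d_ko = np.linalg.norm(
            expr.loc[model.gene_ids].iloc[:, 0] - model.ko_centroid
        )
        d_wt = np.linalg.norm(
            expr.loc[model.gene_ids].iloc[:, 0] - model.wt_centroid
        )
        assert label == (SIGNATURE_LIKE if d_ko < d_wt else SIGNATURE_DIFFERENT)

    def test_invariant_to_gene_order_and_extra_genes(self):
        expr, _ = self._cohort(1.0, seed=3)
        model = build_models(expr, self.sig)
        base = classify_cohort(expr, model)
        shuffled = expr.sample(frac=1, random_state=1)  # permute gene rows
        extra = pd.concat(
            [shuffled, pd.DataFrame(np.zeros((3, expr.shape[1])),
                                    index=["x1", "x2", "x3"],
                                    columns=expr.columns)]
        )
        assert (classify_cohort(extra, model) == base).all()

    def test_label_symmetry_under_global_sign_flip(self):
        expr, _ = self._cohort(1.0, seed=5)
        model = build_models(expr, self.sig)
        labels = classify_cohort(expr, model)
        flipped_sig = self.sig.assign(
            direction=self.sig["direction"].map({"up": "down", "down": "up"})
        )
        flipped_model = build_models(-expr, flipped_sig)
        flipped = classify_cohort(-expr, flipped_model)
        assert (labels == flipped).all()

    def test_accuracy_non_increasing_in_noise(self):
        accs = []
        for noise in (0.5, 2.0, 8.0):
            vals = []
            for seed in range(5):
                expr, truth = self._cohort(noise, seed=seed)
                model = build_models(expr, self.sig)
                vals.append((classify_cohort(expr, model) == truth).mean())
            accs.append(np.mean(vals))
        assert accs[0] >= accs[1] >= accs[2] - 0.02

    def test_matches_sklearn_kmeans(self):
        """Independent check: sklearn k-means from the same initialization."""
        from sklearn.cluster import KMeans

        expr, _ = self._cohort(1.5, seed=8)
        model = build_models(expr, self.sig)
        ours = classify_cohort(expr, model)
        x = expr.loc[model.gene_ids].to_numpy().T
        init = np.vstack([model.wt_centroid, model.ko_centroid])
        km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300).fit(x)
        ko_cluster = np.argmin(
            np.linalg.norm(km.cluster_centers_ - model.ko_centroid.to_numpy(), axis=1)
        )
        theirs = np.where(km.labels_ == ko_cluster, SIGNATURE_LIKE, SIGNATURE_DIFFERENT)
        assert (ours.to_numpy() == theirs).all()

    def test_empty_cohort_fails(self):
        expr, _ = self._cohort(0.0, n=10)
        model = build_models(expr, self.sig)
        with pytest.raises(ValueError, match="empty"):
            classify_cohort(expr.iloc[:, :0], model)


class TestPCA:
    def test_pc1_separates_two_clouds(self):
        expr, truth = TestClassifyCohort()._cohort(0.5)
        coords, var = pca_project(expr.loc[make_signature(4, 4)["gene_id"]])
        like = (truth == SIGNATURE_LIKE).to_numpy()
        assert abs(coords.loc[like, "PC1"].mean() - coords.loc[~like, "PC1"].mean()) > 3
        assert var[0] > var[1]

    def test_duplicated_samples_identical(self):
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 3)),
            index=list("abcde"), columns=["s1", "s2", "s3"],
        )
        dup = pd.concat([expr, expr["s1"].rename("s1b")], axis=1)
        coords, _ = pca_project(dup)
        np.testing.assert_allclose(coords.loc["s1"], coords.loc["s1b"])

    def test_constant_matrix_fails(self):
        expr = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            pca_project(expr)


class TestSurvival:
    def test_identical_groups_null_hr(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, size=200)
        labels = pd.Series([SIGNATURE_LIKE, SIGNATURE_DIFFERENT] * 100)
        res = survival_compare(labels, pd.Series(t), pd.Series(np.ones(200)))
        assert res.ci_lower < 1 < res.ci_upper

    def test_km_step_heights_closed_form(self):
        """No censoring, distinct times: survival drops by 1/n at each event."""
        times = pd.Series([10.0, 20.0, 30.0, 40.0])
        labels = pd.Series([SIGNATURE_LIKE] * 4 + [SIGNATURE_DIFFERENT] * 2)
        res = survival_compare(
            labels,
            pd.concat([times, pd.Series([5.0, 15.0])], ignore_index=True),
            pd.Series(np.ones(6)),
        )
        km = res.km_curves[SIGNATURE_LIKE].set_index("time")["survival"]
        np.testing.assert_allclose(km.loc[[10.0, 20.0, 30.0, 40.0]],
                                   [0.75, 0.5, 0.25, 0.0])

    def test_zero_events_fails(self):
        labels = pd.Series([SIGNATURE_LIKE, SIGNATURE_DIFFERENT])
        with pytest.raises(ValueError, match="events"):
            survival_compare(labels, pd.Series([1.0, 2.0]), pd.Series([0, 0]))

    def test_planted_hazard_recovered(self):
        sig = make_signature(3, 3)
        _, surv, labels = generate_cohort(400, 10, sig, hr=3.0, censor_rate=0.2,
                                          seed=13)
        res = survival_compare(
            labels, surv["time_days"], surv["event"]
        )
        assert res.ci_lower < 3.0 < res.ci_upper
        assert res.hazard_ratio > 1.5


class TestFlagWtstar:
    def _expr(self, n_wt, n_mut, n_wtstar, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(20, 1))
        wt = base + rng.normal(0, 0.1, size=(20, n_wt))
        mut = base + 4 + rng.normal(0, 0.1, size=(20, n_mut))
        wtstar = base + 4 + rng.normal(0, 0.1, size=(20, n_wtstar))
        cols = (
            [f"wt{i}" for i in range(n_wt)]
            + [f"mut{i}" for i in range(n_mut)]
            + [f"ws{i}" for i in range(n_wtstar)]
        )
        expr = pd.DataFrame(np.hstack([wt, mut, wtstar]), columns=cols)
        labels = pd.Series(
            ["WT"] * n_wt + ["MUT"] * n_mut + ["WT"] * n_wtstar, index=cols
        )
        return expr, labels

    def test_separated_groups_flag_nothing(self):
        expr, labels = self._expr(15, 10, 0)
        assert flag_wtstar(expr, labels, seed=0) == []

    def test_planted_wtstar_flagged(self):
        expr, labels = self._expr(15, 10, 10)
        assert sorted(flag_wtstar(expr, labels, seed=0)) == [
            f"ws{i}" for i in range(10)
        ]

    def test_mut_tie_warns_and_flags_nothing(self):
        rng = np.random.default_rng(1)
        # two tight clusters with the MUT cases split evenly between them
        expr = pd.DataFrame(
            np.hstack([rng.normal(0, 0.1, (5, 4)), rng.normal(6, 0.1, (5, 4))]),
            columns=[f"s{i}" for i in range(8)],
        )
        labels = pd.Series(
            ["WT", "WT", "MUT", "MUT", "WT", "WT", "MUT", "MUT"],
            index=expr.columns,
        )
        with pytest.warns(UserWarning, match="evenly"):
            out = flag_wtstar(expr, labels, seed=0)
        assert out == []
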