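"""STAG2-loss gene signature: derivation, patient classification, survival.

The signature is the set of genes differentially expressed upon STAG2 loss
both in patients (STAG2-mutant vs wild-type tumors) and in isogenic cell
clones, with a concordant direction. To classify an independent cohort,
two extreme-phenotype centroids are built on the cohort's own expression
scale: the "KO model" takes, for every up-regulated signature gene, the
maximum expression value observed in the cohort for that gene (the minimum
for down-regulated genes), and the "WT model" is the element-wise opposite.
Two-group k-means seeded at those centroids splits samples into
"signature-like" (nearer the KO model) and "signature-different" groups,
whose overall survival is compared with Kaplan-Meier curves and a Cox
proportional-hazards fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIGNATURE_LIKE = "signature-like"
SIGNATURE_DIFFERENT = "signature-different"


@dataclass
class SignatureModel:
    """Directed signature genes with cohort-scale extreme centroids."""

    genes: pd.DataFrame  # columns: gene_id, direction in {up, down}
    ko_centroid: pd.Series  # indexed by gene_id
    wt_centroid: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ko_centroid.index)


@dataclass
class SurvivalResult:
    """Two-group survival comparison: KM curves plus a Cox PH estimate."""

    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Two-group Cox proportional-hazards comparison",
            f"  groups: " + ", ".join(f"{k} (n={v})" for k, v in self.n_per_group.items()),
            f"  HR ({SIGNATURE_LIKE} vs {SIGNATURE_DIFFERENT}): "
            f"{self.hazard_ratio:.3f} [{self.ci_lower:.3f}, {self.ci_upper:.3f}]",
            f"  p = {self.p_value:.3g}",
        ]
        return "\n".join(lines)


def intersect_degs(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Directed signature: genes significant in both contrasts, same sign.

    Each table needs columns (gene_id, log2fc, fdr). Significance is strict
    (fdr < fdr_max) in both; the shared log2fc sign becomes the direction.
    Genes with discordant signs, or log2fc == 0 in either table, are
    excluded.
    """
    for name, df in (("A", deg_a), ("B", deg_b)):
        if not {"gene_id", "log2fc", "fdr"}.issubset(df.columns):
            raise ValueError(f"contrast {name} lacks gene_id/log2fc/fdr columns")
    merged = deg_a.merge(deg_b, on="gene_id", suffixes=("_a", "_b"))
    sig = merged[(merged["fdr_a"] < fdr_max) & (merged["fdr_b"] < fdr_max)]
    concordant = sig[sig["log2fc_a"] * sig["log2fc_b"] > 0]
    return pd.DataFrame(
        {
            "gene_id": concordant["gene_id"],
            "direction": np.where(concordant["log2fc_a"] > 0, "up", "down"),
        }
    ).reset_index(drop=True)


def build_models(expression: pd.DataFrame, signature: pd.DataFrame) -> SignatureModel:
    """Build KO/WT extreme centroids on the cohort's expression scale.

    ``expression`` is genes x samples (gene_id index); for each signature
    gene present, the KO centroid takes the cohort maximum when the gene is
    up-regulated and the minimum when down-regulated, and the WT centroid
    the opposite. Signature genes absent from the cohort are dropped with a
    warning (cross-platform cohorts rarely share the full gene set).
    """
    present = signature[signature["gene_id"].isin(expression.index)]
    n_missing = len(signature) - len(present)
    if len(present) == 0:
        raise ValueError("no signature genes present in the cohort expression table")
    if n_missing:
        warnings.warn(f"{n_missing} signature genes absent from cohort; dropped")
    sub = expression.loc[present["gene_id"]]
    gmax = sub.max(axis=1)
    gmin = sub.min(axis=1)
    up = (present["direction"] == "up").to_numpy()
    ko = pd.Series(np.where(up, gmax, gmin), index=present["gene_id"])
    wt = pd.Series(np.where(up, gmin, gmax), index=present["gene_id"])
    return SignatureModel(genes=present.reset_index(drop=True), ko_centroid=ko, wt_centroid=wt)


def _lloyd_two_means(
    x: np.ndarray, init: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd iterations for k=2 with explicit tie-break toward cluster 0.

    Returns (assignments, centroids). An emptied cluster keeps its previous
    centroid. Deterministic: no randomness enters after initialization.
    """
    centroids = init.astype(float).copy()
    assign = None
    for _ in range(max_iter):
        d0 = np.linalg.norm(x - centroids[0], axis=1)
        d1 = np.linalg.norm(x - centroids[1], axis=1)
        new_assign = (d1 < d0).astype(int)  # ties (d1 == d0) go to cluster 0
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in (0, 1):
            members = x[assign == k]
            if len(members):
                centroids[k] = members.mean(axis=0)
    return assign, centroids


def classify_cohort(
    expression: pd.DataFrame, model: SignatureModel, seed: int = 0
) -> pd.Series:
    """Label cohort samples signature-like / signature-different.

    Runs k-means (k=2, Euclidean, Lloyd iterations to convergence) on the
    signature-gene expression of each sample, with centroids initialized at
    the WT and KO model vectors. Samples in the cluster whose *converged*
    centroid lies nearer the KO model are labeled signature-like. Distance
    ties during assignment break toward the WT-model cluster (conservative:
    a sample is only called signature-like when strictly nearer).

    ``seed`` is accepted for interface symmetry; the procedure is
    deterministic given the initialization.
    """
    if expression.shape[1] == 0:
        raise ValueError("empty cohort")
    sub = expression.reindex(model.gene_ids)
    if sub.isna().any().any():
        raise ValueError("cohort expression lacks some model genes")
    x = sub.to_numpy(dtype=float).T  # samples x genes
    init = np.vstack([model.wt_centroid.to_numpy(), model.ko_centroid.to_numpy()])
    assign, centroids = _lloyd_two_means(x, init)
    ko_vec = model.ko_centroid.to_numpy()
    ko_cluster = int(
        np.argmin([np.linalg.norm(centroids[k] - ko_vec) for k in (0, 1)])
    )
    labels = np.where(assign == ko_cluster, SIGNATURE_LIKE, SIGNATURE_DIFFERENT)
    return pd.Series(labels, index=expression.columns, name="label")


def pca_project(expression: pd.DataFrame, n_components: int = 2):
    """Project samples onto principal components of signature expression.

    Expression is genes x samples; genes are centered and the SVD taken.
    Sign convention: within each component the loading of largest magnitude
    is made positive, so projections are reproducible across runs. Returns
    (coordinates DataFrame samples x PCs, explained-variance fractions).
    """
    if expression.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    x = expression.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant expression matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u[:, :k] * s[:k]
    var_frac = (s**2 / (s**2).sum())[:k]
    frame = pd.DataFrame(
        coords, index=expression.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, var_frac


def survival_compare(
    labels: pd.Series, time: pd.Series, event: pd.Series
) -> SurvivalResult:
    """Kaplan-Meier curves per group and a two-group Cox PH fit.

    ``labels`` holds the two group names; the hazard ratio reported is for
    signature-like relative to signature-different (or, generally, for the
    lexicographically later group when the signature labels are absent).
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    # positional: callers pass equal-length sequences in matching order
    df = pd.DataFrame(
        {
            "label": np.asarray(labels),
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=float),
        }
    ).dropna()
    groups = sorted(df["label"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if df["event"].sum() == 0:
        raise ValueError("no events observed; survival comparison undefined")
    if SIGNATURE_LIKE in groups:
        risk_group = SIGNATURE_LIKE
    else:
        risk_group = groups[-1]
    km_curves = {}
    for g, grp in df.groupby("label"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(g))
        km_curves[str(g)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(g): "survival"}
        )
    cox_df = df.assign(group=(df["label"] == risk_group).astype(int))[
        ["time", "event", "group"]
    ]
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="time", event_col="event")
    s = cph.summary.loc["group"]
    return SurvivalResult(
        hazard_ratio=float(np.exp(s["coef"])),
        ci_lower=float(np.exp(s["coef lower 95%"])),
        ci_upper=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]),
        km_curves=km_curves,
        n_per_group=df["label"].value_counts().to_dict(),
    )


def flag_wtstar(
    expression: pd.DataFrame, mutation_labels: pd.Series, seed: int = 0,
    n_pcs: int = 2,
) -> list[str]:
    """Flag wild-type samples whose transcriptome clusters with mutants.

    Runs 2-group k-means on the top principal components of the full
    expression matrix; WT samples landing in the cluster that contains the
    majority of MUT samples are returned (the "WT*" cases). A MUT tie
    between clusters yields no flags, with a warning.
    """
    from sklearn.cluster import KMeans

    labels = mutation_labels.reindex(expression.columns)
    present = set(labels.unique())
    if not {"WT", "MUT"}.issubset(present):
        raise ValueError(f"need both WT and MUT labels, got {sorted(present)}")
    coords, _ = pca_project(expression, n_components=n_pcs)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(coords.to_numpy())
    mut_mask = (labels == "MUT").to_numpy()
    counts = [int(np.sum(assign[mut_mask] == k)) for k in (0, 1)]
    if counts[0] == counts[1]:
        warnings.warn("MUT samples split evenly between clusters; no WT* flagged")
        return []
    mut_cluster = int(np.argmax(counts))
    wt_mask = (labels == "WT").to_numpy()
    return list(expression.columns[wt_mask & (assign == mut_cluster)])
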