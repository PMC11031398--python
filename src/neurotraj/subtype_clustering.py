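"""Two-modality clustering of clinical disease trajectories.

Donors are clustered by the similarity of their trajectories using two
complementary featurizations:

* a **flattened matrix** — per donor, the number of observation-years of
  each attribute over the whole lifespan (qualitative information: which
  signs/symptoms, how persistently);
* a **temporal matrix** — the same counts inside overlapping age bins
  (default width 30 years stepped by 5: ages 15-45, 20-50, 25-55, ...),
  capturing *when* the symptomatology manifested. Bins are half-open
  ``[start, start + width)`` so each observation age falls in exactly
  ``width/step`` consecutive bins.

Each matrix is normalized (per-donor totals), log-transformed, feature
standardized and reduced by PCA. The two PCA embeddings are fused with a
weighted-nearest-neighbor (WNN) scheme: per donor, each modality earns a
weight from how much better its own neighbors predict its profile than the
other modality's neighbors do (softmax-normalized, summing to 1). The
weighted affinities define a joint kNN graph, clustered by Leiden
modularity optimization; UMAP supplies 2-D coordinates for visualization
only.

Cluster interpretation uses one-sided Fisher exact tests (diagnosis and
inaccurate-CD overrepresentation; two-sided for APOE4/4 under/over),
cluster-vs-rest rank-sum marker detection on both matrices, and a
subclustering re-run of the full pipeline on donor subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .crossdisorder_stats import mwu_test
from .trajectory_builder import Trajectory

__all__ = [
    "JointGraph",
    "ClusterAssignment",
    "build_matrices",
    "normalize_scale_pca",
    "wnn_graph",
    "cluster_graph",
    "embed_2d",
    "fisher_overrepresentation",
    "find_markers",
    "cluster_cohort",
    "subcluster",
]


# ---------------------------------------------------------------------------
# featurization


def build_matrices(
    trajectories: Mapping[str, Trajectory],
    donors: Sequence[str] | None = None,
    bin_width: int = 30,
    bin_step: int = 5,
    max_age: int | None = None,
    control_donors: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the flattened and temporal count matrices.

    Uses concrete-age presence rows (imputed rows included — imputation is
    part of trajectory preparation). When ``control_donors`` is given, a
    non-control donor without any concrete-age observation raises — such
    donors should have been removed by the cohort filters.
    """
    donor_ids = sorted(trajectories) if donors is None else list(donors)
    attributes = sorted(
        {
            a
            for d in donor_ids
            for a in trajectories[d].frame.loc[
                trajectories[d].frame["present"] == 1, "attribute"
            ]
        }
    )
    if max_age is None:
        # Grid spans 0 to the cohort's maximum age at death (fallback: last
        # observed age) so late-life bins exist for every donor.
        ages = []
        for d in donor_ids:
            trajectory = trajectories[d]
            if trajectory.age_at_death is not None:
                ages.append(float(trajectory.age_at_death))
            elif len(trajectory.frame):
                ages.append(float(trajectory.frame["age"].max()))
        max_age = int(np.nanmax(ages)) if ages else bin_width
    bin_starts = list(range(0, max(max_age - bin_width, 0) + bin_step, bin_step))

    flat = pd.DataFrame(0, index=donor_ids, columns=attributes, dtype=int)
    temporal_cols = [
        f"{a}|{s}-{s + bin_width}" for a in attributes for s in bin_starts
    ]
    temporal = pd.DataFrame(0, index=donor_ids, columns=temporal_cols, dtype=int)
    controls = set(control_donors) if control_donors is not None else None

    for donor_id in donor_ids:
        frame = trajectories[donor_id].frame
        frame = frame[(frame["present"] == 1) & frame["age"].notna()]
        if frame.empty:
            if controls is not None and donor_id not in controls:
                raise ValueError(
                    f"non-control donor {donor_id!r} has no concrete-age "
                    "observations; apply cohort filters first"
                )
            continue
        for attribute, block in frame.groupby("attribute"):
            ages_observed = block["age"].to_numpy(dtype=float)
            flat.loc[donor_id, attribute] = len(ages_observed)
            for s in bin_starts:
                in_bin = int(
                    np.sum((ages_observed >= s) & (ages_observed < s + bin_width))
                )
                if in_bin:
                    temporal.loc[donor_id, f"{attribute}|{s}-{s + bin_width}"] = in_bin
    return flat, temporal


def normalize_scale_pca(
    matrix: pd.DataFrame, n_components: int = 30
) -> pd.DataFrame:
    """Totals-normalize, log1p, z-scale, PCA.

    Per-donor counts are scaled to the median library size, log-transformed
    and standardized per feature (zero-variance features dropped); PCA uses
    a full deterministic SVD. ``n_components`` beyond the data rank is
    truncated with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 donors")
    X = matrix.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    median_total = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scaled = np.divide(
        X * median_total,
        totals[:, None],
        out=np.zeros_like(X),
        where=totals[:, None] > 0,
    )
    logged = np.log1p(scaled)
    variances = logged.var(axis=0)
    keep = variances > 0
    if not keep.any():
        raise ValueError("no non-constant feature")
    logged = logged[:, keep]
    standardized = (logged - logged.mean(axis=0)) / logged.std(axis=0)

    rank = min(standardized.shape[0] - 1, standardized.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncated",
            stacklevel=2,
        )
        n_components = rank
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(
        standardized
    )
    return pd.DataFrame(
        scores,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )


# ---------------------------------------------------------------------------
# weighted nearest neighbors


@dataclass
class JointGraph:
    donor_ids: list[str]
    weights: pd.DataFrame  # columns weight_flat, weight_temporal; rows sum to 1
    edges: list[tuple[int, int, float]]  # undirected, weighted
    embeddings: dict[str, pd.DataFrame]
    k: int

    def to_igraph(self) -> ig.Graph:
        graph = ig.Graph(n=len(self.donor_ids))
        graph.add_edges([(i, j) for i, j, _ in self.edges])
        graph.es["weight"] = [w for _, _, w in self.edges]
        return graph


def _knn(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    return dist[:, 1:], idx[:, 1:]  # drop self


def wnn_graph(
    embedding_flat: pd.DataFrame,
    embedding_temporal: pd.DataFrame,
    k: int = 20,
) -> JointGraph:
    """Fuse two modality embeddings into a weighted joint kNN graph.

    Per donor, modality weights come from within- vs cross-modality
    neighborhood predictiveness: modality m scores
    ``exp(-d(x_m, mean of m-neighbors)/sigma) - exp(-d(x_m, mean of
    other-modality neighbors)/sigma)`` and the two scores are softmaxed.
    Identical modalities therefore get weights (0.5, 0.5) exactly.
    """
    if not embedding_flat.index.equals(embedding_temporal.index):
        raise ValueError("embeddings must be row-aligned")
    n = len(embedding_flat)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of donors ({n})")
    X = {"flat": embedding_flat.to_numpy(), "temporal": embedding_temporal.to_numpy()}
    dist = {}
    idx = {}
    for m in X:
        dist[m], idx[m] = _knn(X[m], k)

    eps = 1e-12
    scores = {}
    for m in X:
        other = "temporal" if m == "flat" else "flat"
        pred_within = X[m][idx[m]].mean(axis=1)
        pred_cross = X[m][idx[other]].mean(axis=1)
        d_within = np.linalg.norm(X[m] - pred_within, axis=1)
        d_cross = np.linalg.norm(X[m] - pred_cross, axis=1)
        sigma = dist[m][:, -1] + eps  # bandwidth: distance to k-th neighbor
        scores[m] = np.exp(-d_within / sigma) - np.exp(-d_cross / sigma)

    exp_scores = np.exp(
        np.column_stack([scores["flat"], scores["temporal"]])
    )
    weights = exp_scores / exp_scores.sum(axis=1, keepdims=True)
    weight_frame = pd.DataFrame(
        weights,
        index=embedding_flat.index,
        columns=["weight_flat", "weight_temporal"],
    )

    # Joint affinity with per-donor modality weights and local bandwidths.
    affinity = np.zeros((n, n))
    for col, m in enumerate(("flat", "temporal")):
        pairwise = np.linalg.norm(X[m][:, None, :] - X[m][None, :, :], axis=2)
        sigma = dist[m][:, -1][:, None] + eps
        affinity += weights[:, col : col + 1] * np.exp(-pairwise / sigma)
    np.fill_diagonal(affinity, 0.0)

    edge_weights: dict[tuple[int, int], float] = {}
    order = np.argsort(-affinity, axis=1)[:, :k]
    for i in range(n):
        for j in order[i]:
            key = (min(i, int(j)), max(i, int(j)))
            edge_weights[key] = max(
                edge_weights.get(key, 0.0), float(affinity[i, j])
            )
    edges = [(i, j, w) for (i, j), w in sorted(edge_weights.items())]
    return JointGraph(
        donor_ids=list(embedding_flat.index),
        weights=weight_frame,
        edges=edges,
        embeddings={"flat": embedding_flat, "temporal": embedding_temporal},
        k=k,
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterAssignment:
    labels: pd.Series  # donor -> cluster id (int)
    weights: pd.DataFrame | None = None
    coordinates: pd.DataFrame | None = None  # umap_x, umap_y

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def to_frame(self) -> pd.DataFrame:
        frame = self.labels.rename("cluster").to_frame()
        if self.weights is not None:
            frame = frame.join(self.weights)
        if self.coordinates is not None:
            frame = frame.join(self.coordinates)
        return frame


def cluster_graph(
    graph: JointGraph, resolution: float = 0.8, seed: int = 0
) -> ClusterAssignment:
    """Leiden modularity clustering of the joint graph."""
    g = graph.to_igraph()
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = pd.Series(
        partition.membership, index=pd.Index(graph.donor_ids, name="donor_id")
    )
    return ClusterAssignment(labels=labels, weights=graph.weights)


def embed_2d(graph: JointGraph, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP of the weighted joint embedding. Visualization only: no
    statistic downstream depends on these coordinates."""
    import umap  # deferred: slow import

    w = graph.weights.to_numpy()
    Z = np.hstack(
        [
            np.sqrt(w[:, 0:1]) * graph.embeddings["flat"].to_numpy(),
            np.sqrt(w[:, 1:2]) * graph.embeddings["temporal"].to_numpy(),
        ]
    )
    n_neighbors = min(graph.k, len(Z) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about fixed random_state
        coords = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=seed
        ).fit_transform(Z)
    return pd.DataFrame(
        coords, index=graph.weights.index, columns=["umap_x", "umap_y"]
    )


# ---------------------------------------------------------------------------
# cluster interpretation


def fisher_overrepresentation(
    assignment: ClusterAssignment | pd.Series,
    categories: Mapping[str, str] | pd.Series,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact tests for category overrepresentation per cluster.

    One-sided ("greater") for diagnosis / inaccurate-CD enrichment;
    two-sided for APOE4/4 over- *or* under-representation. BH-FDR across
    the whole cluster x category panel.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    cats = pd.Series(categories).reindex(labels.index)
    if cats.isna().any():
        raise ValueError("every clustered donor needs a category label")
    rows = []
    for cluster in sorted(labels.unique()):
        in_cluster = labels == cluster
        if in_cluster.sum() == 0:
            raise ValueError(f"cluster {cluster} is empty")
        for category in sorted(cats.unique()):
            in_cat = cats == category
            a = int((in_cluster & in_cat).sum())
            b = int((in_cluster & ~in_cat).sum())
            c = int((~in_cluster & in_cat).sum())
            d = int((~in_cluster & ~in_cat).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append(
                {
                    "cluster": cluster,
                    "category": category,
                    "n_in_cluster": a,
                    "odds_ratio": float(odds),
                    "p": float(p),
                }
            )
    frame = pd.DataFrame(rows)
    frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame


def find_markers(
    matrix: pd.DataFrame,
    assignment: ClusterAssignment | pd.Series,
) -> pd.DataFrame:
    """Cluster-vs-rest two-sided rank-sum tests per feature.

    Run separately on the flattened and the temporal matrix. Singleton
    clusters are skipped with a warning. BH-FDR across the whole panel;
    ``direction`` is "up" when the cluster mean exceeds the rest.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    labels = labels.reindex(matrix.index)
    rows = []
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cluster {cluster} has <2 donors; skipped", stacklevel=2)
            continue
        if (~mask).sum() < 2:
            warnings.warn(f"cluster {cluster} complement too small; skipped", stacklevel=2)
            continue
        inside = matrix.loc[mask]
        outside = matrix.loc[~mask]
        for feature in matrix.columns:
            x = inside[feature].to_numpy(dtype=float)
            y = outside[feature].to_numpy(dtype=float)
            if np.all(x == x[0]) and np.all(y == x[0]):
                continue  # identically constant: untestable, q would be 1
            u, p = mwu_test(x, y)
            rows.append(
                {
                    "cluster": cluster,
                    "feature": feature,
                    "U": u,
                    "p": p,
                    "direction": "up" if x.mean() > y.mean() else "down",
                    "mean_in": float(x.mean()),
                    "mean_out": float(y.mean()),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["cluster", "feature", "U", "p", "direction", "mean_in", "mean_out"]
    )
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = pd.Series(dtype=float)
    return frame


# ---------------------------------------------------------------------------
# end-to-end pipelines


def cluster_cohort(
    flat: pd.DataFrame,
    temporal: pd.DataFrame,
    n_components: int = 30,
    k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    compute_umap: bool = False,
    modalities: str = "both",
) -> ClusterAssignment:
    """Matrices -> PCA -> WNN -> Leiden, optionally with UMAP coordinates.

    ``modalities="flat"`` (or ``"temporal"``) runs a single-modality
    control: the same donor graph built from one embedding only — used to
    show that the temporal modality is necessary to separate onset-shifted
    symptom programs.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        emb_flat = normalize_scale_pca(flat, n_components)
        emb_temporal = normalize_scale_pca(temporal, n_components)
    if modalities == "flat":
        emb_temporal = emb_flat
    elif modalities == "temporal":
        emb_flat = emb_temporal
    elif modalities != "both":
        raise ValueError(f"unknown modalities {modalities!r}")
    k_eff = min(k, len(flat) - 1)
    if k_eff < k:
        warnings.warn(f"k shrunk to {k_eff} for {len(flat)} donors", stacklevel=2)
    graph = wnn_graph(emb_flat, emb_temporal, k=k_eff)
    assignment = cluster_graph(graph, resolution=resolution, seed=seed)
    if compute_umap:
        assignment.coordinates = embed_2d(graph, seed=seed)
    return assignment


def subcluster(
    flat: pd.DataFrame,
    temporal: pd.DataFrame,
    parent: ClusterAssignment,
    clusters: Iterable[int],
    **pipeline_kwargs,
) -> ClusterAssignment:
    """Re-run the full pipeline on the donors of one or more parent
    clusters (e.g. merged early- and late-onset dementia clusters).

    Neighbor counts shrink automatically (with a warning) when the subset
    is small relative to ``k``.
    """
    members: list[str] = []
    for cluster in clusters:
        members.extend(parent.members(cluster))
    if len(members) < 3:
        raise ValueError("subset too small to subcluster")
    sub_flat = flat.loc[members]
    sub_temporal = temporal.loc[members]
    # Drop attribute columns that became all-zero in the subset.
    sub_flat = sub_flat.loc[:, sub_flat.sum(axis=0) > 0]
    sub_temporal = sub_temporal.loc[:, sub_temporal.sum(axis=0) > 0]
    return cluster_cohort(sub_flat, sub_temporal, **pipeline_kwargs)
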