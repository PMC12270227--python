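"""Feature reduction, embedding, similarity and clustering of fingerprints.

Two complementary reductions are used on fingerprint matrices:

* collinearity-based selection — drop zero-variance features, then
  iteratively remove one member of every feature pair with |Pearson r|
  above a cut (default 0.8), keeping a provenance record sufficient to
  replay the reduction (this is the interpretable per-feature view);
* UMAP embedding — the full concatenated fingerprints projected to a small
  number of components (default 100) with the correlation metric and 10
  neighbors (the view used for density clustering).

Downstream, a Pearson similarity matrix feeds HDBSCAN (distance =
1 − r, sign-aware) and complete-linkage hierarchical clustering, with
exports for tree-view software and network tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.cluster import HDBSCAN

from .core import CPScreenError, get_logger

log = get_logger(__name__)

DEFAULT_COLLINEARITY_CUT = 0.8
UMAP_DEFAULTS = {"n_components": 100, "metric": "correlation", "n_neighbors": 10}


@dataclass
class ReducedFingerprintMatrix:
    """A reduced matrix plus the provenance needed to replay the reduction."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def removed_features(self) -> list[str]:
        return self.provenance.get("removed_features", [])

    def replay(self, original: pd.DataFrame) -> pd.DataFrame:
        """Re-apply the recorded removals to the original matrix."""
        keep = [c for c in original.columns if c not in set(self.removed_features)]
        return original[keep]


def drop_zero_variance(matrix: pd.DataFrame) -> ReducedFingerprintMatrix:
    """Remove features with zero standard deviation across all treatments."""
    if len(matrix) < 1:
        raise CPScreenError("empty matrix")
    sd = matrix.std(axis=0, ddof=0)
    removed = [c for c in matrix.columns if sd[c] == 0.0]
    if len(removed) == len(matrix.columns):
        raise CPScreenError("all features have zero variance")
    kept = matrix.drop(columns=removed)
    return ReducedFingerprintMatrix(
        data=kept,
        provenance={"method": "drop_zero_variance", "removed_features": removed},
    )


def remove_collinear(
    matrix: pd.DataFrame, r_cut: float = DEFAULT_COLLINEARITY_CUT
) -> ReducedFingerprintMatrix:
    """Iteratively remove collinear features until no pair has |Pearson r|
    above ``r_cut``.

    Pairs are processed in descending |r| (stable name tie-break); from each
    pair the member with the higher mean absolute correlation to all
    remaining features is removed (name tie-break: the lexicographically
    later one goes).  The removal order is fixed so provenance replay is
    exact.
    """
    if not 0.0 < r_cut < 1.0:
        raise CPScreenError(f"r_cut={r_cut} not in (0, 1)")
    if len(matrix) < 3:
        raise CPScreenError("need at least 3 rows for correlations")
    cols = list(matrix.columns)
    corr = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)
    alive = np.ones(len(cols), dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(alive)[0]
        if sub.size < 2:
            break
        block = corr[np.ix_(sub, sub)]
        r_max = block.max()
        if r_max <= r_cut:
            break
        # candidate pairs at the current maximum |r|; stable name tie-break
        ii, jj = np.where(np.isclose(block, r_max))
        pairs = sorted(
            {tuple(sorted((cols[sub[a]], cols[sub[b]]))) for a, b in zip(ii, jj) if a < b}
        )
        name_a, name_b = pairs[0]
        idx = {c: k for k, c in enumerate(cols)}
        mean_r = {
            n: block[list(sub).index(idx[n])].sum() / (sub.size - 1) for n in (name_a, name_b)
        }
        if mean_r[name_a] > mean_r[name_b]:
            victim = name_a
        elif mean_r[name_b] > mean_r[name_a]:
            victim = name_b
        else:
            victim = max(name_a, name_b)
        alive[idx[victim]] = False
        removed.append(victim)
    kept = [c for c, a in zip(cols, alive) if a]
    return ReducedFingerprintMatrix(
        data=matrix[kept],
        provenance={
            "method": "remove_collinear",
            "r_cut": r_cut,
            "removed_features": removed,
        },
    )


def concat_conditions(
    matrix_resting: pd.DataFrame, matrix_activated: pd.DataFrame
) -> pd.DataFrame:
    """Column-wise concatenation of per-condition fingerprints with
    condition-suffixed feature names (482 + 482 → 964 in the reduced view)."""
    if list(matrix_resting.index) != list(matrix_activated.index):
        only_r = sorted(set(matrix_resting.index) - set(matrix_activated.index))[:5]
        only_a = sorted(set(matrix_activated.index) - set(matrix_resting.index))[:5]
        raise CPScreenError(
            f"row keys differ between conditions (resting-only {only_r}, "
            f"activated-only {only_a}) or are ordered differently"
        )
    left = matrix_resting.rename(columns={c: f"{c}::resting" for c in matrix_resting.columns})
    right = matrix_activated.rename(
        columns={c: f"{c}::activated" for c in matrix_activated.columns}
    )
    return pd.concat([left, right], axis=1)


def split_conditions(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`concat_conditions`."""
    rest = matrix[[c for c in matrix.columns if c.endswith("::resting")]]
    act = matrix[[c for c in matrix.columns if c.endswith("::activated")]]
    rest = rest.rename(columns=lambda c: c[: -len("::resting")])
    act = act.rename(columns=lambda c: c[: -len("::activated")])
    return rest, act


def umap_embed(
    matrix: pd.DataFrame,
    n_components: int = UMAP_DEFAULTS["n_components"],
    metric: str = UMAP_DEFAULTS["metric"],
    n_neighbors: int = UMAP_DEFAULTS["n_neighbors"],
    seed: int = 0,
) -> ReducedFingerprintMatrix:
    """UMAP projection of fingerprints; deterministic under a fixed seed.

    All parameters are pinned and recorded in provenance; other UMAP
    parameters are left at library defaults.
    """
    import umap  # deferred: numba compilation is slow to import

    if len(matrix) < n_neighbors + 1:
        raise CPScreenError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {len(matrix)}"
        )
    reducer = umap.UMAP(
        n_components=n_components,
        metric=metric,
        n_neighbors=n_neighbors,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        # fixing random_state forces single-threaded UMAP; the trade of
        # parallelism for determinism is deliberate
        warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
        emb = reducer.fit_transform(matrix.to_numpy(dtype=float))
    data = pd.DataFrame(
        emb, index=matrix.index, columns=[f"UMAP{i + 1}" for i in range(n_components)]
    )
    return ReducedFingerprintMatrix(
        data=data,
        provenance={
            "method": "umap",
            "n_components": n_components,
            "metric": metric,
            "n_neighbors": n_neighbors,
            "seed": seed,
        },
    )


def similarity_matrix(matrix: pd.DataFrame, metric: str = "pearson") -> pd.DataFrame:
    """Square row-similarity matrix (Pearson r, or negative Euclidean
    distance).  Zero-variance rows under Pearson are flagged and left
    missing."""
    if len(matrix) < 2:
        raise CPScreenError("need at least 2 rows for a similarity matrix")
    x = matrix.to_numpy(dtype=float)
    if metric == "pearson":
        sd = x.std(axis=1)
        flat = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.corrcoef(x)
        if flat.any():
            log.warning(
                "similarity_matrix: %d zero-variance rows flagged missing: %s",
                int(flat.sum()), list(matrix.index[flat]),
            )
            sim[flat, :] = np.nan
            sim[:, flat] = np.nan
        np.fill_diagonal(sim, 1.0)
    elif metric == "euclidean":
        from scipy.spatial.distance import cdist

        sim = -cdist(x, x)
    else:
        raise CPScreenError(f"unknown metric {metric!r}")
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def cluster_hdbscan(
    similarity: pd.DataFrame, min_cluster_size: int = 5
) -> pd.Series:
    """HDBSCAN on a similarity matrix, converted to distance = 1 − s
    (clipped at 0); label −1 marks noise.  Cluster count and noise fraction
    go to the log."""
    if len(similarity) < 5:
        raise CPScreenError("need at least 5 rows for HDBSCAN")
    if similarity.shape[0] != similarity.shape[1]:
        raise CPScreenError("similarity matrix must be square")
    dist = np.clip(1.0 - similarity.to_numpy(dtype=float), 0.0, None)
    dist = 0.5 * (dist + dist.T)  # enforce exact symmetry
    np.fill_diagonal(dist, 0.0)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed", copy=True).fit_predict(dist)
    n_clusters = len(set(labels) - {-1})
    noise = float((labels == -1).mean())
    log.info("HDBSCAN: %d clusters, %.0f%% noise", n_clusters, 100 * noise)
    out = pd.Series(labels, index=similarity.index, name="cluster")
    out.attrs["n_clusters"] = n_clusters
    out.attrs["noise_fraction"] = noise
    return out


def cluster_hdbscan_euclidean(matrix: pd.DataFrame, min_cluster_size: int = 5) -> pd.Series:
    """HDBSCAN directly on rows with Euclidean distances (the metric used
    for the consolidation-entropy clustering)."""
    if len(matrix) < 5:
        raise CPScreenError("need at least 5 rows for HDBSCAN")
    labels = HDBSCAN(min_cluster_size=min_cluster_size, metric="euclidean", copy=True).fit_predict(
        matrix.to_numpy(dtype=float)
    )
    out = pd.Series(labels, index=matrix.index, name="cluster")
    out.attrs["n_clusters"] = len(set(labels) - {-1})
    out.attrs["noise_fraction"] = float((labels == -1).mean())
    return out


def _pearson_distance_condensed(x: np.ndarray) -> np.ndarray:
    sim = np.corrcoef(x)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return squareform(0.5 * (dist + dist.T), checks=False)


def cluster_hierarchical(matrix: pd.DataFrame, axis: str = "rows"):
    """Complete-linkage hierarchical clustering on 1 − Pearson r distance.

    Returns (linkage matrix, leaf labels in dendrogram order); leaf order is
    deterministic (scipy's stable merge ordering).
    """
    if axis == "columns":
        matrix = matrix.T
    labels = list(matrix.index)
    if len(labels) < 2:
        raise CPScreenError("need at least 2 leaves")
    z = sch.linkage(_pearson_distance_condensed(matrix.to_numpy(dtype=float)), method="complete")
    order = sch.leaves_list(z)
    return z, [labels[i] for i in order]


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(z)

    def rec(node):
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return rec(tree) + ";"


def compartment_sorted_columns(columns: list[str]) -> list[str]:
    """Group feature columns by compartment prefix (ER_, Nuc_, Mito_, ...)
    keeping the within-group order stable."""
    prefixes: list[str] = []
    for c in columns:
        p = c.split("_")[0] + "_"
        if p not in prefixes:
            prefixes.append(p)
    return [c for p in prefixes for c in columns if c.startswith(p)]


def export_heatmap(
    matrix: pd.DataFrame,
    row_linkage,
    col_linkage,
    out_prefix: str | Path,
    compartment_sort: bool = False,
) -> dict[str, Path]:
    """Write a clustered matrix (TSV) plus row/column trees (newick) for
    tree-view software; optionally group columns by compartment prefix
    instead of the column dendrogram order."""
    if len(matrix) == 0:
        raise CPScreenError("cannot export an empty matrix")
    out_prefix = Path(out_prefix)
    row_z, row_order = row_linkage
    if len(row_order) != len(matrix.index) or set(row_order) != set(matrix.index):
        raise CPScreenError("row tree leaves do not match matrix rows")
    if compartment_sort:
        col_order = compartment_sorted_columns(list(matrix.columns))
        col_z = None
    else:
        col_z, col_order = col_linkage
        if set(col_order) != set(matrix.columns):
            raise CPScreenError("column tree leaves do not match matrix columns")
    clustered = matrix.loc[row_order, col_order]
    paths = {"matrix": out_prefix.with_suffix(".clustered.tsv")}
    clustered.to_csv(paths["matrix"], sep="\t", index_label="key")
    paths["row_tree"] = out_prefix.with_suffix(".rows.nwk")
    paths["row_tree"].write_text(_linkage_to_newick(row_z, list(matrix.index)) + "\n")
    if col_z is not None:
        paths["col_tree"] = out_prefix.with_suffix(".cols.nwk")
        paths["col_tree"].write_text(_linkage_to_newick(col_z, list(matrix.columns)) + "\n")
    return paths


def export_edge_list(
    similarity: pd.DataFrame, cut: float, path: str | Path
) -> pd.DataFrame:
    """Similarity-above-cut edge list CSV for network tools (e.g. Cytoscape)."""
    keys = list(similarity.index)
    s = similarity.to_numpy(dtype=float)
    rows = [
        {"source": keys[i], "target": keys[j], "similarity": float(s[i, j])}
        for i in range(len(keys))
        for j in range(i + 1, len(keys))
        if np.isfinite(s[i, j]) and s[i, j] > cut
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "similarity"])
    df.to_csv(path, index=False)
    return df
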