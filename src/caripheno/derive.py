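"""De-novo re-derivation of tooth-surface clusters by hierarchical clustering.

Given surface-level records, each of the 128 index surfaces becomes a binary
variable (affected / not affected) across subjects.  Surfaces with similar
susceptibility *patterns* — i.e. correlated affection indicators — are merged
agglomeratively: the distance between two surfaces is 1 minus the Pearson
correlation of their indicators, and Ward linkage builds the tree, which is
cut at a fixed number of clusters (default 5).  Correlation distance, rather
than a prevalence-based metric, groups surfaces by *pattern* of caries
experience rather than by raw caries rate.

Edentulous subjects are constant rows (every surface affected) and carry no
pattern information, so they are excluded by default.  Surfaces that are
constant across the remaining subjects have undefined correlations; they are
attached to the cluster of their nearest non-constant surface by Hamming
distance.

The derivation is used to validate that a predefined cluster structure is
recoverable from data with known ground truth; agreement between partitions
is measured by the adjusted Rand index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .clusters import ClusterMap
from .dentition import SubjectRecord, enumerate_index_surfaces
from .phenotypes import index_counts


def surface_affection_matrix(
    records: list[SubjectRecord], drop_edentulous: bool = True
) -> np.ndarray:
    """Subjects x 128 binary matrix (1 = decayed/filled/missing) in canonical order."""
    if not records:
        raise ValueError("empty cohort")
    universe = enumerate_index_surfaces()
    if drop_edentulous:
        records = [r for r in records if not index_counts(r).edentulous]
    X = np.zeros((len(records), len(universe)), dtype=np.int8)
    for i, rec in enumerate(records):
        for j, key in enumerate(universe):
            X[i, j] = 1 if rec.surfaces[key].affected else 0
    return X


def derive_clusters(
    matrix: np.ndarray, k: int = 5
) -> tuple[ClusterMap, pd.DataFrame]:
    """Agglomerative clustering of the 128 surface columns into k clusters.

    Returns the derived :class:`ClusterMap` (labels 1..k) together with the
    merge history (child indices and merge heights from the linkage tree).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 128:
        raise ValueError("matrix must be subjects x 128")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects to derive clusters")
    if not 1 <= k <= 128:
        raise ValueError("k must be in 1..128")

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all surface columns are constant; no pattern to cluster")

    corr = np.corrcoef(X[:, keep], rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels_kept = fcluster(Z, t=min(k, int(keep.sum())), criterion="maxclust")

    labels = np.zeros(128, dtype=int)
    kept_idx = np.flatnonzero(keep)
    labels[kept_idx] = labels_kept
    # constant columns inherit the cluster of the nearest informative column
    for j in np.flatnonzero(~keep):
        hamming = np.abs(X[:, [j]] - X[:, kept_idx]).mean(axis=0)
        labels[j] = labels[kept_idx[int(hamming.argmin())]]

    universe = enumerate_index_surfaces()
    cluster_map = ClusterMap(
        name=f"derived_k{k}",
        assignment={key: int(labels[j]) for j, key in enumerate(universe)},
    )
    history = pd.DataFrame(Z, columns=["child_a", "child_b", "height", "size"])
    return cluster_map, history[["child_a", "child_b", "height"]]


def adjusted_rand(map_a: ClusterMap, map_b: ClusterMap) -> float:
    """Adjusted-for-chance Rand index between two surface partitions.

    1.0 for identical partitions (up to relabeling), ~0 for chance-level
    agreement.  Both maps must cover the same 128-surface universe (the
    :class:`ClusterMap` constructor enforces this).
    """
    universe = enumerate_index_surfaces()
    a = [map_a.assignment[key] for key in universe]
    b = [map_b.assignment[key] for key in universe]
    return float(adjusted_rand_score(a, b))
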