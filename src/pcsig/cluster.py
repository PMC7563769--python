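"""Hierarchical clustering of samples on a gene signature.

The visual heat-map judgment — "do the samples group by cell line or by
overexpression status?" — is formalized as a concordance score: the best
achievable agreement between a k-cut of the dendrogram and the factor's
levels over all cluster-to-level bijections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

DISTANCES = ("euclidean", "pearson")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterResult:
    """Agglomeration of samples: scipy linkage matrix plus display order."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    distance: str
    linkage: str

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) at a k-cluster cut."""
        if k > len(self.sample_ids):
            raise ValueError(f"cannot cut {len(self.sample_ids)} samples into {k} clusters")
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def sample_distance_matrix(
    matrix: pd.DataFrame, distance: str = "pearson", center_genes: bool = True
) -> np.ndarray:
    """Condensed distance vector between sample columns.

    ``pearson`` is the 1 - r dissimilarity over the signature genes, the
    usual expression-heat-map metric; ``euclidean`` is available for score
    space or raw intensities. With ``center_genes`` (the default, matching
    row-scaled heat-map displays) each gene row is mean-centered first: the
    shared baseline intensity otherwise dominates between-sample correlation
    and hides condition contrasts that shift all signature genes the same
    way.
    """
    if center_genes and matrix.shape[1] > 1:
        values = matrix.to_numpy(dtype=float)
        matrix = pd.DataFrame(
            values - values.mean(axis=1, keepdims=True),
            index=matrix.index,
            columns=matrix.columns,
        )
    if distance == "euclidean":
        return pdist(matrix.to_numpy(dtype=float).T, metric="euclidean")
    if distance == "pearson":
        values = matrix.to_numpy(dtype=float).T
        if matrix.shape[0] < 2:
            # correlation undefined on a single gene; fall back to euclidean
            return pdist(values, metric="euclidean")
        sd = values.std(axis=1)
        if np.any(sd == 0):
            # constant samples: treat via small jitter-free limit, r := 0
            corr = np.corrcoef(values)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.corrcoef(values)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        return squareform(dist, checks=False)
    raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    method: str = "average",
    center_genes: bool = True,
) -> ClusterResult:
    """Agglomerate the samples of ``matrix`` (typically signature genes only).

    Ward linkage requires euclidean distances and is rejected with pearson.
    The result is deterministic for a given input.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    if matrix.shape[0] < 1:
        raise ValueError("clustering needs at least 1 gene")
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    condensed = sample_distance_matrix(matrix, distance, center_genes=center_genes)
    z = linkage(condensed, method=method)
    order = dendrogram(z, no_plot=True)["leaves"]
    sample_ids = list(matrix.columns)
    return ClusterResult(
        linkage_matrix=z,
        sample_ids=sample_ids,
        leaf_order=[sample_ids[i] for i in order],
        distance=distance,
        linkage=method,
    )


def cluster_concordance(
    result: ClusterResult, labels: pd.Series, k: int | None = None
) -> float:
    """Best bijective agreement between a k-cut and a factor, in [0, 1].

    ``labels`` maps sample id -> factor level; ``k`` defaults to the number
    of levels. The score maximizes, over all bijections from clusters to
    levels, the fraction of samples whose cluster maps to their true level —
    exact enumeration over k! assignments, which is cheap for the 2-3 levels
    these designs have. Invariant under relabeling on either side.
    """
    labels = labels.loc[result.sample_ids].astype(str)
    levels = sorted(labels.unique())
    if k is None:
        k = len(levels)
    if k != len(levels):
        raise ValueError(f"k={k} but factor has {len(levels)} levels")
    clusters = result.cut(k)
    cluster_ids = sorted(clusters.unique())
    # contingency counts cluster x level
    table = pd.crosstab(clusters, labels)
    table = table.reindex(index=cluster_ids, columns=levels, fill_value=0)
    n = len(labels)
    best = 0
    for perm in permutations(range(len(levels))):
        hits = sum(
            table.iloc[i, perm[i]] for i in range(min(len(cluster_ids), len(levels)))
        )
        best = max(best, hits)
    return best / n


def two_way_order(matrix: pd.DataFrame, distance: str = "pearson",
                  method: str = "average") -> pd.DataFrame:
    """Reorder both genes and samples by their dendrograms (heat-map layout)."""
    samples = hierarchical_cluster(matrix, distance=distance, method=method)
    genes = hierarchical_cluster(matrix.T, distance=distance, method=method)
    return matrix.loc[genes.leaf_order, samples.leaf_order]
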