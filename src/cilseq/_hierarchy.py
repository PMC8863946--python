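"""Shared agglomerative clustering used by every stage that draws a sample tree.

All dendrograms in the package (mutation matrix, amplified genes, methylation
correlation, marker-panel spots) use average linkage (UPGMA) on a precomputed
condensed distance vector.  Leaves are sorted lexicographically before linkage
so that merge order, and hence the serialized tree, is deterministic for a
given set of labelled observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    """Agglomerative tree over labelled samples.

    ``merges`` is the scipy linkage matrix (n-1 rows: left id, right id,
    height, size); ``labels`` are the leaf names in the row order that
    linkage saw (sorted lexicographically).
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment at ``n_clusters`` groups."""
        assign = cut_tree(self.merges, n_clusters=n_clusters).ravel()
        return dict(zip(self.labels, (int(a) for a in assign)))

    def root_split(self) -> tuple[set[str], set[str]]:
        """The two clades joined by the final merge."""
        two = self.cut(2)
        a = {s for s, c in two.items() if c == 0}
        b = {s for s, c in two.items() if c == 1}
        return a, b

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            i, j = int(i), int(j)
            bl_i = h - height[i]
            bl_j = h - height[j]
            node[n + k] = f"({node[i]}:{bl_i:g},{node[j]}:{bl_j:g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame, metric: str = "euclidean"
) -> Dendrogram:
    """Average-linkage tree over the rows of ``matrix`` (rows = samples).

    ``metric`` is any scipy pdist metric, or ``"pearson"`` for 1 - r
    correlation distance.  Requires >= 2 rows.
    """
    if matrix.shape[0] < 2:
        raise ValueError("hierarchical clustering needs at least 2 samples")
    ordered = matrix.sort_index()
    x = ordered.to_numpy(dtype=float)
    if metric == "pearson":
        d = pdist(x, metric="correlation")  # 1 - r
        d = np.clip(d, 0.0, None)
    else:
        d = pdist(x, metric=metric)
    merges = linkage(d, method="average")
    return Dendrogram(merges=merges, labels=[str(i) for i in ordered.index])


def pairwise_pearson(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of the rows of ``matrix``."""
    ordered = matrix.sort_index()
    r = 1.0 - squareform(pdist(ordered.to_numpy(dtype=float), metric="correlation"))
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ordered.index, columns=ordered.index)
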