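"""Spatial-spot expression clustering.

A spot-by-gene unique-molecular-identifier count matrix is normalized so
every spot's total equals the median spot total, partitioned by seeded
K-means (K = 10 by default), and selected spots are hierarchically clustered
on a marker-gene panel (median-normalized, log1p-transformed, Euclidean
average linkage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._hierarchy import Dendrogram, hierarchical_cluster

logger = logging.getLogger(__name__)


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each spot so its total count equals the median spot total.

    The median is taken over the original totals of the retained spots;
    zero-total spots are dropped (and logged) before computing it.  Within-
    spot proportions are preserved exactly.
    """
    totals = matrix.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("dropping %d zero-total spots", int(zero.sum()))
    kept = matrix.loc[~zero]
    if kept.shape[0] < 1:
        raise ValueError("no spots with nonzero totals")
    med = float(kept.sum(axis=1).median())
    return kept.mul(med / kept.sum(axis=1), axis=0)


def kmeans_spots(matrix: pd.DataFrame, k: int = 10, seed: int = 0,
                 n_init: int = 10) -> tuple[pd.Series, float]:
    """Seeded K-means partition of spots; labels are 1..k.

    Runs ``n_init`` k-means++ restarts and keeps the best inertia; fully
    deterministic for a fixed seed and input order.  Returns (labels,
    inertia).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if matrix.shape[0] < k:
        raise ValueError(f"{matrix.shape[0]} spots cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    return (pd.Series(labels + 1, index=matrix.index, name="cluster"),
            float(km.inertia_))


def panel_cluster(matrix: pd.DataFrame, selected_spots: list[str],
                  panel_genes: list[str], *, normalize: bool = True,
                  log_transform: bool = True) -> Dendrogram:
    """Average-linkage tree of selected spots on a marker-gene panel.

    Expression is median-normalized across all spots first (so selection
    does not change scale factors), then restricted to the panel and log1p
    transformed; distances are Euclidean.
    """
    if not selected_spots:
        raise ValueError("empty spot selection")
    missing = [g for g in panel_genes if g not in matrix.columns]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing}")
    data = median_normalize(matrix) if normalize else matrix
    sub = data.loc[[s for s in selected_spots if s in data.index], panel_genes]
    if log_transform:
        sub = np.log1p(sub)
    return hierarchical_cluster(sub, metric="euclidean")
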