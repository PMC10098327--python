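"""Shared-nearest-neighbor graph construction + Leiden community detection.

One clustering contract serves both the expression embedding and the
transition-profile embedding: k nearest neighbours in Euclidean space,
Jaccard-weighted shared-neighbour edges pruned below 1/15, and Leiden
modularity (RBConfiguration) at a caller-chosen resolution with a fixed
seed.  This mirrors the graph clustering used by the mainstream
single-cell toolkits.
"""

from __future__ import annotations

import warnings

import numpy as np

DEFAULT_N_NEIGHBORS = 15
SNN_PRUNE = 1.0 / 15.0


def snn_leiden(
    X: np.ndarray,
    resolution: float,
    seed: int,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
) -> np.ndarray:
    """Cluster rows of ``X``; returns string labels '0', '1', ... numbered
    by first cell occurrence.  Deterministic for a fixed seed."""
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    if n == 0:
        return np.empty(0, dtype=object)
    if n == 1:
        return np.array(["0"], dtype=object)
    k = n_neighbors
    if k >= n:
        warnings.warn(f"fewer cells ({n}) than neighborhood size {n_neighbors}; using k={n - 1}")
        k = n - 1

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # neighbour sets include the cell itself (first hit on fitted data)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w >= SNN_PRUNE:
                edges.append(key)
                weights.append(w)

    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # stable relabelling by first occurrence so labels do not depend on
    # leidenalg's internal community numbering
    relabel: dict[int, str] = {}
    labels = np.empty(n, dtype=object)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = str(len(relabel))
        labels[i] = relabel[c]
    return labels
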