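"""Density-based clustering and local-density estimation.

Implements a deterministic DBSCAN variant: the classical definition (a core
point has >= ``min_points`` neighbours within ``eps`` *including itself*;
clusters are the density-connected components of core points) except that
border points reachable from several clusters are assigned to the cluster of
their *nearest* core point, which makes the labelling independent of input
order.  Cluster ids are canonicalized by order of each cluster's lowest
member index.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .exceptions import ParameterError

NOISE = -1


def neighbor_counts(points: np.ndarray, radius: float,
                    include_self: bool = True) -> np.ndarray:
    """Number of points within ``radius`` of each point."""
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = np.asarray(tree.query_ball_point(pts, radius, return_length=True))
    return counts if include_self else counts - 1


def local_density(points: np.ndarray, radius: float) -> np.ndarray:
    """Per-point local density: neighbours within ``radius`` (self excluded)
    divided by the search-disc area pi * radius**2 (localizations / nm^2)."""
    counts = neighbor_counts(points, radius, include_self=False)
    return counts / (np.pi * radius ** 2)


def dbscan_labels(points: np.ndarray, eps: float, min_points: int) -> np.ndarray:
    """Deterministic DBSCAN labels; noise points get label -1.

    ``min_points`` counts the point itself (MATLAB convention).
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if min_points < 1:
        raise ParameterError("min_points must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels

    tree = cKDTree(pts)
    counts = np.asarray(tree.query_ball_point(pts, eps, return_length=True))
    core = counts >= min_points
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels

    # connected components of core points within eps
    core_tree = cKDTree(pts[core_idx])
    pairs = core_tree.query_pairs(eps, output_type="ndarray")
    n_core = len(core_idx)
    if len(pairs):
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n_core, n_core))
    else:
        graph = coo_matrix((n_core, n_core))
    _, comp = connected_components(graph, directed=False)
    labels[core_idx] = comp

    # border points: nearest core point within eps decides the cluster
    border_idx = np.flatnonzero(~core)
    if len(border_idx):
        dist, nearest = core_tree.query(pts[border_idx], k=1,
                                        distance_upper_bound=eps * (1 + 1e-12))
        reachable = np.isfinite(dist) & (dist <= eps)
        labels[border_idx[reachable]] = comp[nearest[reachable]]

    # canonical ids: clusters numbered by their lowest member index
    assigned = labels >= 0
    if assigned.any():
        order = {}
        for i in np.flatnonzero(assigned):
            order.setdefault(labels[i], len(order))
        labels[assigned] = np.vectorize(order.get)(labels[assigned])
    return labels
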