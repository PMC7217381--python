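"""PCA with elbow selection, SNN-weighted KNN graph, Louvain, 2-D layouts.

The clustering graph is a k-nearest-neighbor graph (Euclidean metric in
PC space) whose edge weights are normalized shared-neighbor counts: the
neighbor list of a cell contains the cell itself plus its k nearest
neighbors (distance ties broken by ascending cell index), an edge (i, j)
exists when either cell is in the other's list, and its weight is
|L(i) & L(j)| / (k + 1), hence in [0, 1] with weight 1 for cells with
identical neighborhoods.  Communities are found by seeded greedy
modularity optimization (Louvain) on the weighted graph.
"""

from __future__ import annotations

import logging
import random as _random
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

log = logging.getLogger("mkbias")


@dataclass
class Embedding:
    coords: np.ndarray       # cells x d
    variances: np.ndarray    # length d, non-increasing
    components: np.ndarray   # d x genes
    mean: np.ndarray         # gene means used for centering


def run_pca(X: np.ndarray, n_components: int = 50) -> Embedding:
    """PCA of a cells x genes matrix after gene centering.

    Deterministic up to exact arithmetic: component signs are fixed by
    making the largest-magnitude loading of each component positive.
    If fewer than n_components+1 cells are available the dimension is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    n_cells, n_genes = X.shape
    max_d = min(n_cells - 1, n_genes)
    if n_components > max_d:
        warnings.warn(f"reducing n_components from {n_components} to {max_d}")
        n_components = max_d
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    coords = U * S
    variances = S**2 / max(n_cells - 1, 1)
    return Embedding(coords=coords, variances=variances, components=Vt, mean=mean)


def choose_n_pcs(variances: np.ndarray, override: int | None = None,
                 default: int = 20) -> int:
    """Elbow selection: the index maximizing perpendicular distance to the
    line joining the first and last variance points.

    ``override`` short-circuits the geometry (the pipeline default is 20
    components).  A flat or strictly linear spectrum has no elbow and
    falls back to ``default`` with a warning.
    """
    if override is not None:
        return int(override)
    v = np.asarray(variances, dtype=np.float64)
    if len(v) < 3:
        raise ValueError("need at least 3 variances for elbow selection")
    x = np.arange(len(v), dtype=np.float64)
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (v - v[0]) - dy * (x - x[0])) / norm
    if dist.max() <= 1e-12 * max(abs(v).max(), 1.0):
        warnings.warn("no elbow in the variance spectrum; using default")
        return min(default, len(v))
    return int(np.argmax(dist))


@dataclass
class SNNGraph:
    weights: sp.csr_matrix   # symmetric, zero diagonal, weights in [0, 1]
    k: int
    neighbor_lists: sp.csr_matrix  # cells x cells membership incl. self

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


def _knn_indices(coords: np.ndarray, k: int, block: int = 512) -> np.ndarray:
    """k nearest neighbors (excluding self) by Euclidean distance, ties
    broken by ascending cell index via stable sort."""
    n = coords.shape[0]
    sq = (coords**2).sum(axis=1)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] - 2.0 * coords[start:stop] @ coords.T + sq[None, :]
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def build_snn_graph(coords: np.ndarray, k: int = 30) -> SNNGraph:
    """Build the shared-nearest-neighbor weighted graph over cells."""
    if k <= 0:
        raise ValueError("k must be positive")
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = _knn_indices(coords, k)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.arange(n)[:, None], nn], axis=1).ravel()
    M = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    shared = (M @ M.T).tocsr()
    pattern = ((M + M.T) > 0).astype(np.float64).tolil()
    pattern.setdiag(0.0)
    pattern = pattern.tocsr()
    pattern.eliminate_zeros()
    W = pattern.multiply(shared) / (k + 1.0)
    W = sp.csr_matrix(W)
    return SNNGraph(weights=W, k=k, neighbor_lists=M)


def louvain_cluster(graph: SNNGraph, seed: int = 0,
                    resolution: float = 1.0) -> "ClusterAssignment":
    """Seeded Louvain community detection on the weighted SNN graph.

    Labels are relabeled contiguously from 0 in order of first
    appearance, so the assignment is stable under cluster permutation.
    """
    import igraph as ig

    W = sp.triu(graph.weights, k=1).tocoo()
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=graph.n_cells, edges=list(zip(W.row.tolist(), W.col.tolist())))
    rng = _random.Random(seed)
    ig.set_random_number_generator(rng)
    try:
        part = g.community_multilevel(weights=W.data.tolist(), resolution=resolution)
    finally:
        ig.set_random_number_generator(_random)
    membership = np.asarray(part.membership)
    labels = _canonical_labels(membership)
    modularity = g.modularity(membership.tolist(), weights=W.data.tolist())
    log.info("louvain: %d clusters, modularity %.4f (seed=%d resolution=%g)",
             labels.max() + 1, modularity, seed, resolution)
    return ClusterAssignment(labels=labels, modularity=float(modularity),
                             seed=seed, resolution=resolution)


def _canonical_labels(membership: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(membership)
    for i, m in enumerate(membership):
        if m not in mapping:
            mapping[m] = len(mapping)
        out[i] = mapping[m]
    return out


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    modularity: float
    seed: int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def merge_clusters(assignment: ClusterAssignment,
                   merge_map: dict[int, int]) -> ClusterAssignment:
    """Apply an explicit, logged cluster-merge mapping (old -> new labels).

    Merging similar clusters is a curated, configuration-supplied step,
    never an automatic heuristic; it can only reduce the cluster count.
    """
    labels = np.array([merge_map.get(int(l), int(l)) for l in assignment.labels])
    labels = _canonical_labels(labels)
    log.info("cluster merge %s: %d -> %d clusters", merge_map,
             assignment.n_clusters, int(labels.max()) + 1)
    return ClusterAssignment(labels=labels, modularity=assignment.modularity,
                             seed=assignment.seed, resolution=assignment.resolution)


def embed_2d(data, method: str = "umap", seed: int = 0, **params) -> np.ndarray:
    """2-D layout for visualization only; delegated to established
    implementations with the parameters recorded in the log.

    method='umap' expects PC coordinates (defaults: 30 neighbors, cosine
    metric); method='fdg' expects an :class:`SNNGraph` and runs a seeded
    force-directed spring layout on the weighted graph.
    """
    if method == "umap":
        import umap

        opts = {"n_neighbors": 30, "metric": "cosine"}
        opts.update(params)
        log.info("umap layout: %s seed=%d", opts, seed)
        reducer = umap.UMAP(n_components=2, random_state=seed, **opts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(reducer.fit_transform(np.asarray(data)))
    if method == "fdg":
        import networkx as nx

        if not isinstance(data, SNNGraph):
            raise ValueError("fdg layout requires an SNNGraph")
        opts = {"iterations": 50}
        opts.update(params)
        log.info("force-directed layout: %s seed=%d", opts, seed)
        G = nx.from_scipy_sparse_array(data.weights)
        pos = nx.spring_layout(G, seed=seed, weight="weight", **opts)
        return np.array([pos[i] for i in range(data.n_cells)])
    raise ValueError(f"unknown embedding method {method!r}")
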