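"""Diffusion-map pseudotime and expression profiles along a lineage path.

A Gaussian kernel with adaptive bandwidth (distance to the ceil(k/2)-th
neighbor) is built on the kNN graph in PC space, symmetrized and
density-normalized, and the top eigenvectors of the resulting
transition operator (excluding the trivial constant one), scaled by
their eigenvalues, give diffusion coordinates.  Pseudotime is the
Euclidean diffusion distance from a root cell (the cell maximizing an
HSC signature score by default), rescaled to [0, 1]; cells disconnected
from the root's component get infinite pseudotime.  Expression profiles
along a designated path of clusters are running averages over cells
ordered by pseudotime.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .cluster import _knn_indices

log = logging.getLogger("mkbias")


@dataclass
class DiffusionMap:
    coords: np.ndarray        # cells x n_comps (eigenvalue-scaled)
    eigenvalues: np.ndarray   # of the transition operator, descending
    component: np.ndarray     # connected-component label per cell


def diffusion_map(coords: np.ndarray, k: int = 30, n_comps: int = 10) -> DiffusionMap:
    """Diffusion coordinates from a kNN Gaussian kernel with adaptive
    bandwidth; eigenvalues of the transition operator lie in (-1, 1]
    with the top one equal to 1."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = _knn_indices(coords, k)
    d = np.sqrt(((coords[:, None, :] - coords[nn]) ** 2).sum(axis=2)) if n * k < 2_000_000 else None
    if d is None:  # block-wise distances for large inputs
        d = np.empty((n, k))
        for i in range(n):
            d[i] = np.sqrt(((coords[nn[i]] - coords[i]) ** 2).sum(axis=1))
    sigma = np.maximum(d[:, int(np.ceil(k / 2)) - 1], 1e-12)

    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    aff = np.exp(-(d.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = sp.csr_matrix((aff, (rows, cols)), shape=(n, n))
    W = (W + W.T) * 0.5

    n_comp_graph, comp_labels = connected_components(W, directed=False)
    if n_comp_graph > 1:
        log.warning("diffusion map: %d disconnected components", n_comp_graph)

    q = np.asarray(W.sum(axis=1)).ravel()
    Dq_inv = sp.diags(1.0 / np.maximum(q, 1e-300))
    K = Dq_inv @ W @ Dq_inv                      # density normalization
    d2 = np.asarray(K.sum(axis=1)).ravel()
    Dh = sp.diags(1.0 / np.sqrt(np.maximum(d2, 1e-300)))
    A = Dh @ K @ Dh                              # symmetric conjugate of P
    m = min(n_comps + 1, n - 2)
    v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic ARPACK start vector
    evals, evecs = eigsh(A, k=m, which="LA", v0=v0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = (Dh @ evecs)
    # deterministic sign: largest-|entry| coordinate positive
    flip = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    flip[flip == 0] = 1.0
    psi = psi * flip
    # accumulated-transition scaling lambda/(1-lambda): distances in this
    # space sum the kernel over all diffusion times, so slow (trajectory)
    # components dominate fast (noise) ones
    lam = np.clip(evals[1:], None, 1.0 - 1e-9)
    dm = psi[:, 1:] * (lam / (1.0 - lam))
    return DiffusionMap(coords=dm, eigenvalues=evals, component=comp_labels)


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray
    root: int
    diffusion: DiffusionMap


def pseudotime_from_root(dmap: DiffusionMap, root: int | None = None,
                         root_scores: np.ndarray | None = None) -> PseudotimeResult:
    """Pseudotime = Euclidean distance from the root in diffusion space,
    rescaled so the farthest connected cell is at 1 and the root at 0.

    The root is an explicit cell index or the cell maximizing
    ``root_scores`` (an HSC signature score); ties break to the lowest
    index.  Cells in other connected components get infinite pseudotime.
    """
    if root is None:
        if root_scores is None:
            raise ValueError("provide an explicit root or root_scores")
        root = int(np.argmax(root_scores))
    t = np.sqrt(((dmap.coords - dmap.coords[root]) ** 2).sum(axis=1))
    t[dmap.component != dmap.component[root]] = np.inf
    finite = np.isfinite(t)
    tmax = t[finite].max()
    if tmax > 0:
        t[finite] = t[finite] / tmax
    return PseudotimeResult(pseudotime=t, root=root, diffusion=dmap)


def path_profile(X_norm: np.ndarray, pseudotime: np.ndarray, labels,
                 path_clusters, n_avg: int = 5000) -> pd.DataFrame:
    """Running-average expression profiles along an ordered cluster path.

    Cells are restricted to the path's clusters and ordered by
    pseudotime (ties by cell index); each gene is smoothed with a
    running mean of window ``n_avg`` (truncated to the path length, a
    window larger than the path collapses to one global mean with a
    warning).  A window of 1 returns the ordered raw values.
    """
    labels = np.asarray(labels)
    path_clusters = list(path_clusters)
    if not path_clusters:
        raise ValueError("empty path")
    on_path = np.isin(labels, path_clusters)
    if not on_path.any():
        raise ValueError("no cells on the requested path")
    idx = np.where(on_path)[0]
    t = np.asarray(pseudotime)[idx]
    order = idx[np.lexsort((idx, t))]
    V = np.asarray(X_norm)[order]  # cells_on_path x genes
    n_path = V.shape[0]
    w = int(n_avg)
    if w > n_path:
        warnings.warn(f"window {w} exceeds path size {n_path}; using global mean")
        w = n_path
    if w < 1:
        raise ValueError("n_avg must be >= 1")
    csum = np.vstack([np.zeros((1, V.shape[1])), np.cumsum(V, axis=0)])
    smooth = (csum[w:] - csum[:-w]) / w
    return pd.DataFrame(smooth.T, index=None)


def rank_trend_genes(X_norm: np.ndarray, pseudotime: np.ndarray,
                     candidate_genes, gene_names) -> pd.DataFrame:
    """Spearman correlation of expression with pseudotime per candidate
    gene (e.g. a transcription-factor list), ranked by |rho| with the
    direction of change reported.  Constant genes get rho = 0."""
    t = np.asarray(pseudotime, dtype=float)
    if np.all(t == t[0]):
        raise ValueError("pseudotime is constant")
    gene_names = pd.Index(gene_names)
    cand = [g for g in candidate_genes if g in gene_names]
    if not cand:
        raise ValueError("no candidate genes present")
    X = np.asarray(X_norm)
    tr = stats.rankdata(t)
    tr_c = tr - tr.mean()
    denom_t = np.sqrt((tr_c**2).sum())
    rows = []
    for g in cand:
        v = X[:, gene_names.get_loc(g)]
        if np.all(v == v[0]):
            rho = 0.0
        else:
            vr = stats.rankdata(v)
            vr_c = vr - vr.mean()
            rho = float((tr_c * vr_c).sum() / (denom_t * np.sqrt((vr_c**2).sum())))
        rows.append({"gene": g, "rho": rho,
                     "direction": "up" if rho > 0 else ("down" if rho < 0 else "flat")})
    out = pd.DataFrame(rows)
    return out.reindex(out["rho"].abs().sort_values(ascending=False, kind="stable").index
                       ).reset_index(drop=True)
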