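"""Gene-set scoring, lineage assignment, AUC gating, contaminant removal.

Two score kinds are used: the per-cell mean of log-normalized expression
over a lineage gene set (the "lineage gene score"), and a per-cell area
under the recovery curve of a set within the top fraction of that
cell's expression ranking (AUCell-style, bounded in [0, 1]).  Lineage
assignment follows the gray/uncommitted rule: a cell is labeled with
the unique lineage whose score exceeds its threshold and "uncommitted"
when zero or more than one do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("mkbias")

UNCOMMITTED = "uncommitted"


def bundled_genesets() -> dict[str, "GeneSet"]:
    """Editable TSV fixtures shipped with the package (fibrosis,
    proliferation, pDC).  These are synthetic stand-ins for curated
    signatures and are meant to be replaced for real analyses."""
    from importlib import resources

    from .io import read_geneset_tsv

    sets: dict[str, GeneSet] = {}
    root = resources.files("mkbias") / "data" / "genesets"
    for entry in sorted(root.iterdir()):
        if entry.name.endswith(".tsv"):
            for name, genes in read_geneset_tsv(str(entry)).items():
                sets[name] = GeneSet(name, genes, note=f"bundled: {entry.name}")
    return sets


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate identifiers")


@dataclass
class ScoreVector:
    values: pd.Series
    kind: str          # 'mean' | 'auc'
    gene_set: str
    missing: list[str] = field(default_factory=list)


def _present_genes(adata: ad.AnnData, gene_set: GeneSet) -> tuple[list[str], list[str]]:
    known = set(adata.var_names)
    present = [g for g in gene_set.genes if g in known]
    missing = [g for g in gene_set.genes if g not in known]
    if missing:
        log.warning("gene set %s: %d identifiers not in matrix: %s",
                    gene_set.name, len(missing), missing[:10])
    if not present:
        raise ValueError(
            f"no genes of set {gene_set.name!r} present; missing: {missing}")
    return present, missing


def score_geneset_mean(adata: ad.AnnData, gene_set: GeneSet) -> ScoreVector:
    """Per-cell mean of log-normalized expression over the set's genes."""
    present, missing = _present_genes(adata, gene_set)
    X = adata[:, present].X
    vals = np.asarray(X.mean(axis=1)).ravel() if sp.issparse(X) else np.asarray(X).mean(axis=1)
    return ScoreVector(values=pd.Series(vals, index=adata.obs_names),
                       kind="mean", gene_set=gene_set.name, missing=missing)


def default_lineage_thresholds(scores: dict[str, ScoreVector],
                               control_mask: np.ndarray,
                               quantile: float = 0.9) -> dict[str, float]:
    """Per-lineage threshold = the given quantile of control-group scores."""
    return {name: float(np.quantile(sv.values.values[control_mask], quantile))
            for name, sv in scores.items()}


def assign_lineage(scores: dict[str, ScoreVector],
                   thresholds: dict[str, float] | float) -> pd.Series:
    """Label each cell with the unique lineage whose score exceeds its
    threshold, or 'uncommitted' when zero or >= 2 lineages exceed."""
    names = list(scores)
    index = scores[names[0]].values.index
    for sv in scores.values():
        if not sv.values.index.equals(index):
            raise ValueError("score vectors cover different cell sets")
    if np.isscalar(thresholds):
        thresholds = {name: float(thresholds) for name in names}
    above = np.column_stack(
        [scores[n].values.values > thresholds[n] for n in names])
    n_above = above.sum(axis=1)
    winner = np.array(names, dtype=object)[np.argmax(above, axis=1)]
    labels = np.where(n_above == 1, winner, UNCOMMITTED)
    return pd.Series(labels, index=index, name="lineage")


def aucell_score(adata: ad.AnnData, gene_set: GeneSet, top_frac: float = 0.05,
                 seed: int = 0) -> ScoreVector:
    """Area under the recovery curve of the set within each cell's top ranks.

    Genes are ranked per cell by decreasing expression, ties broken by a
    seeded shuffle followed by a stable sort.  With T = ceil(top_frac *
    n_genes), the recovery curve counts set genes found among the top r
    ranks for r = 1..T; its area is normalized by the maximal area (all
    set genes at the very top), giving a score in [0, 1] that is
    invariant to monotone transformations of the cell's expression.
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    present, missing = _present_genes(adata, gene_set)
    n_genes = adata.n_vars
    T = math.ceil(top_frac * n_genes)
    set_idx = adata.var_names.get_indexer(present)
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    rng = np.random.default_rng(seed)
    tie_key = rng.permutation(n_genes)

    n_set = len(set_idx)
    max_auc = sum(T - s for s in range(min(n_set, T)))
    scores = np.zeros(adata.n_obs)
    for c in range(adata.n_obs):
        order = np.lexsort((tie_key, -X[c]))   # rank 0 = highest expression
        ranks = np.empty(n_genes, dtype=np.int64)
        ranks[order] = np.arange(n_genes)
        r = ranks[set_idx]
        r = r[r < T]
        scores[c] = (T - r).sum() / max_auc if max_auc else 0.0
    return ScoreVector(values=pd.Series(scores, index=adata.obs_names),
                       kind="auc", gene_set=gene_set.name, missing=missing)


def gate_cells_by_score(score: ScoreVector, threshold: float = 0.4,
                        direction: str = "greater") -> tuple[pd.Index, pd.Index]:
    """Strict-inequality gate on a score vector; returns (gated, rest)."""
    vals = score.values
    if direction == "greater":
        mask = vals > threshold
    elif direction == "less":
        mask = vals < threshold
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    gated, rest = vals.index[mask], vals.index[~mask]
    log.info("gate %s %s %g: %d gated, %d rest", score.gene_set, direction,
             threshold, len(gated), len(rest))
    return gated, rest


def flag_contaminant_cluster(adata: ad.AnnData, labels: np.ndarray,
                             score: ScoreVector,
                             threshold: float) -> tuple[ad.AnnData, list[int]]:
    """Remove clusters whose mean contaminant-signature score strictly
    exceeds ``threshold`` (boundary clusters are retained); downstream
    stages are expected to re-run on the reduced matrix."""
    labels = np.asarray(labels)
    if len(labels) != adata.n_obs:
        raise ValueError("cluster labels and matrix are not aligned")
    vals = score.values.values
    removed = [int(c) for c in np.unique(labels)
               if vals[labels == c].mean() > threshold]
    keep = ~np.isin(labels, removed)
    if not keep.any():
        raise ValueError("contaminant rule would remove every cluster")
    for c in removed:
        log.info("contaminant cluster %d removed (%d cells)", c,
                 int((labels == c).sum()))
    return adata[keep].copy(), removed
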