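"""Preranked gene-set enrichment with a permutation null.

Genes are ranked by a signed significance metric (sign(log2FC) x
-log10 combined p).  For each gene set the enrichment score (ES) is the
extreme of the weighted Kolmogorov-Smirnov running sum (hit increments
proportional to |metric|^weight, uniform miss decrements).  The null is
built by permuting gene labels; NES divides ES by the mean |null ES| of
matching sign, and the FDR q-value follows the standard sign-stratified
procedure over the pooled normalized null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("mkbias")


def rank_genes(de_table: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Ranking metric = sign(log2FC) * -log10(p_combined), descending;
    ties broken by |log2FC| (descending) then gene id."""
    if len(de_table) == 0:
        raise ValueError("empty differential-expression table")
    df = de_table.copy()
    p = np.clip(df["p_combined"].astype(float).values, p_floor, 1.0)
    sign = np.sign(df["log2FC"].astype(float).values)
    sign[sign == 0] = 1.0
    df["metric"] = sign * -np.log10(p)
    df["_abs_lfc"] = df["log2FC"].abs()
    df = df.sort_values(["metric", "_abs_lfc", "gene"],
                        ascending=[False, False, True], kind="stable")
    return df[["gene", "metric"]].reset_index(drop=True)


def enrichment_score(metrics: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted KS running-sum ES over a ranked list.

    Returns (ES, extreme position).  |ES| <= 1 by construction.
    """
    metrics = np.asarray(metrics, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(metrics)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a strict non-empty subset of the ranking")
    w = np.abs(metrics) ** weight
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hit_mask.astype(float)
        total = float(n_hit)
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~hit_mask) / (n - n_hit)
    dev = p_hit - p_miss
    pos = int(np.argmax(np.abs(dev)))
    return float(dev[pos]), pos


@dataclass
class EnrichmentRecord:
    name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0


def preranked_gsea(ranking: pd.DataFrame, gene_sets: dict[str, list[str]],
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 15, max_size: int = 500) -> pd.DataFrame:
    """Preranked GSEA over a (gene, metric) ranking.

    Sets outside [min_size, max_size] after intersection are skipped
    with a warning.  Same seed gives identical NES and q.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    genes = ranking["gene"].astype(str).values
    metrics = ranking["metric"].astype(float).values
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        pos = np.array(sorted(index[g] for g in set(members) if g in index), dtype=int)
        if not min_size <= len(pos) <= max_size:
            warnings.warn(f"set {name!r} size {len(pos)} outside "
                          f"[{min_size}, {max_size}]; skipped")
            continue
        kept.append((name, pos))
    if not kept:
        raise ValueError("no gene set overlaps the ranking within size bounds")

    records = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes = []
    for name, pos in kept:
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        es, peak = enrichment_score(metrics, hit, weight)
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            perm_pos = rng.choice(n, size=len(pos), replace=False)
            ph = np.zeros(n, dtype=bool)
            ph[perm_pos] = True
            null_es[i], _ = enrichment_score(metrics, ph, weight)
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = max(int(same.sum()), 1)
        p_nom = max(int((np.abs(null_es[same]) >= abs(es)).sum()), 0) / n_same
        mean_same = np.abs(null_es[same]).mean() if same.any() else np.abs(null_es).mean()
        nes = es / mean_same if mean_same > 0 else 0.0
        null_nes = np.where(null_es >= 0,
                            null_es / max(np.abs(null_es[null_es >= 0]).mean(), 1e-300),
                            null_es / max(np.abs(null_es[null_es < 0]).mean(), 1e-300))
        null_nes_pool.append(null_nes)
        obs_nes.append(nes)
        if es >= 0:
            le = [genes[i] for i in range(peak + 1) if hit[i]]
        else:
            le = [genes[i] for i in range(peak, n) if hit[i]]
        records.append(EnrichmentRecord(name=name, size=len(pos), es=es, nes=nes,
                                        p_nominal=float(p_nom), fdr_q=np.nan,
                                        leading_edge=le, n_perm=n_perm, seed=seed))

    pool = np.concatenate(null_nes_pool)
    obs = np.asarray(obs_nes)
    for rec in records:
        if rec.nes >= 0:
            null_frac = (pool >= rec.nes).sum() / max((pool >= 0).sum(), 1)
            obs_frac = (obs >= rec.nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_frac = (pool <= rec.nes).sum() / max((pool < 0).sum(), 1)
            obs_frac = (obs <= rec.nes).sum() / max((obs < 0).sum(), 1)
        rec.fdr_q = float(min(null_frac / max(obs_frac, 1e-300), 1.0))

    out = pd.DataFrame([{
        "set": r.name, "size": r.size, "ES": r.es, "NES": r.nes,
        "p_nominal": r.p_nominal, "fdr_q": r.fdr_q,
        "leading_edge": ";".join(r.leading_edge),
        "n_perm": r.n_perm, "seed": r.seed,
    } for r in records])
    log.info("gsea: %d sets tested, %d at q < 0.25", len(out),
             int((out["fdr_q"] < 0.25).sum()))
    return out
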