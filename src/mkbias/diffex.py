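"""Combined frequency + level differential expression.

Each gene is tested two ways on the same two groups of cells: a
two-sided Wilcoxon rank-sum test on log-normalized expression levels
and a two-sided Fisher's exact test on the 2x2 table of expressing
(count > 0) cell frequencies.  The two p-values are combined by
Fisher's method (-2 * sum(ln p) ~ chi-square with 2k df) and adjusted
across genes by Benjamini-Hochberg within each comparison.  The two
component tests are positively dependent, so the combined p-value is
taken at face value as in common practice; its empirical null level is
quantified by simulation rather than corrected (see the methods note).
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

log = logging.getLogger("mkbias")

P_FLOOR = 1e-300


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have n <= 8 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value (probability-mass definition)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def fisher_combine(p_values, floor: float = P_FLOOR) -> float:
    """Fisher's method: X^2 = -2 * sum(ln p) vs chi-square with 2k df.

    Zero p-values are clamped to ``floor`` with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        warnings.warn(f"p-values of 0 clamped to {floor}")
        p = np.clip(p, floor, None)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _group_stats(X_norm: np.ndarray, expressing: np.ndarray,
                 mask_in: np.ndarray) -> pd.DataFrame:
    """Per-gene means, expressing fractions and the three p-values for one
    in-group vs rest comparison (vectorized rank-sum, per-gene Fisher)."""
    n_in, n_out = int(mask_in.sum()), int((~mask_in).sum())
    Xi, Xo = X_norm[mask_in], X_norm[~mask_in]
    mean_in, mean_out = Xi.mean(axis=0), Xo.mean(axis=0)
    k_in = expressing[mask_in].sum(axis=0)
    k_out = expressing[~mask_in].sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_w = stats.mannwhitneyu(Xi, Xo, alternative="two-sided",
                                 method="asymptotic", axis=0).pvalue
    p_w = np.nan_to_num(np.asarray(p_w, dtype=float), nan=1.0)
    p_f = np.array([
        fisher_exact_2x2([[ki, n_in - ki], [ko, n_out - ko]])
        for ki, ko in zip(k_in, k_out)
    ])
    x2 = -2.0 * (np.log(np.clip(p_w, P_FLOOR, 1.0))
                 + np.log(np.clip(p_f, P_FLOOR, 1.0)))
    p_c = stats.chi2.sf(x2, df=4)
    return pd.DataFrame({
        "log2FC": mean_in - mean_out,
        "frac_expressing_in": k_in / n_in,
        "frac_expressing_out": k_out / n_out,
        "p_wilcoxon": p_w, "p_fisher": p_f, "p_combined": p_c,
    })


def cluster_markers(adata: ad.AnnData, labels, lfc_min: float = 0.5,
                    q_max: float = 0.05, frac_min: float = 0.3,
                    top_n: int = 50) -> pd.DataFrame:
    """Marker table: each cluster vs all other cells.

    A gene passes the marker filter at |log2FC| >= lfc_min, BH q <
    q_max (BH across genes within the comparison) and in-cluster
    expressing fraction > frac_min; passing genes are ranked by combined
    p then |log2FC| and at most ``top_n`` per cluster are flagged as
    reported markers.  log2FC is the difference of group means of
    log2(1 + x) expression.  Clusters with fewer than 3 cells are
    skipped with a warning.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    expressing = np.asarray((sp.csr_matrix(counts) > 0).todense())
    records = []
    for cl in np.unique(labels):
        mask = labels == cl
        if mask.sum() < 3:
            warnings.warn(f"cluster {cl} has fewer than 3 cells; skipped")
            continue
        df = _group_stats(X, expressing, mask)
        df.insert(0, "gene", adata.var_names)
        df.insert(1, "group", cl)
        df["q_bh"] = bh_adjust(df["p_combined"].values)
        passes = ((df["log2FC"].abs() >= lfc_min) & (df["q_bh"] < q_max)
                  & (df["frac_expressing_in"] > frac_min))
        df["passes_marker_filter"] = passes
        ranked = df[passes].sort_values(
            ["p_combined", "log2FC"], key=lambda s: -s.abs() if s.name == "log2FC" else s,
            kind="stable")
        reported = set(ranked.index[:top_n])
        df["reported_marker"] = df.index.isin(reported)
        records.append(df)
    out = pd.concat(records, ignore_index=True)
    log.info("markers: %d reported across %d clusters",
             int(out["reported_marker"].sum()), len(records))
    return out


def genotype_expression_test(adata: ad.AnnData, genotype, gene: str) -> pd.DataFrame:
    """Pairwise genotype-group comparison for one gene.

    For each pair of genotype groups (e.g. WT-HD / WT-patient / mutant):
    expressing fractions, Fisher's exact test on frequencies, Wilcoxon
    rank-sum on log-normalized levels, and the Fisher's-method
    combination of the two p-values.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not in matrix")
    genotype = pd.Series(np.asarray(genotype), index=adata.obs_names)
    groups = [g for g in genotype.unique() if pd.notna(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty genotype groups")
    gi = adata.var_names.get_loc(gene)
    X = adata.X
    levels = np.asarray(X[:, gi].todense()).ravel() if sp.issparse(X) else np.asarray(X)[:, gi]
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    expr = np.asarray((sp.csr_matrix(counts)[:, gi] > 0).todense()).ravel()

    rows = []
    for g1, g2 in combinations(groups, 2):
        m1, m2 = (genotype == g1).values, (genotype == g2).values
        k1, k2 = int(expr[m1].sum()), int(expr[m2].sum())
        n1, n2 = int(m1.sum()), int(m2.sum())
        p_f = fisher_exact_2x2([[k1, n1 - k1], [k2, n2 - k2]])
        p_w = wilcoxon_rank_sum(levels[m1], levels[m2])
        rows.append({
            "gene": gene, "group_a": g1, "group_b": g2,
            "n_a": n1, "n_b": n2,
            "frac_expressing_a": k1 / n1, "frac_expressing_b": k2 / n2,
            "log2FC": levels[m1].mean() - levels[m2].mean(),
            "p_wilcoxon": p_w, "p_fisher": p_f,
            "p_combined": fisher_combine([p_w, p_f]),
        })
    return pd.DataFrame(rows)


def welch_t_from_summary(mean_a: float, sem_a: float, n_a: int,
                         mean_b: float, sem_b: float, n_b: int) -> tuple[float, float]:
    """Welch two-sample t-test from summary statistics (mean, SEM, N).

    Returns (t, two-sided p) with Welch-Satterthwaite degrees of freedom,
    for comparing group summaries as reported in figures (mean +/- SEM).
    """
    se2 = sem_a**2 + sem_b**2
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / (sem_a**4 / (n_a - 1) + sem_b**4 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
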