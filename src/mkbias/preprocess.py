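"""Pre-clustering stages: QC, normalization, HVG selection, batch adjustment.

QC thresholds follow droplet scRNA-seq convention for this pipeline:
cells are retained with UMI counts strictly above ``min_umi`` (default
1,000) and at most a per-donor maximum, genes detected strictly above
``min_genes`` (default 500), and mitochondrial fraction strictly below
``max_mito`` (default 0.15); genes must be expressed in at least
``min_cells_per_gene`` cells (default 10).  Expression is normalized to
``scale_factor`` (default 10,000) counts per cell and log2(1+x)
transformed.  Highly variable genes are selected by fitting the squared
coefficient of variation against 1/mean with a gamma GLM (identity
link), scoring each gene by its excess CV^2 over the fitted technical
trend.  Donor effects are removed by a parametric empirical-Bayes
location/scale adjustment of the standardized expression matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("mkbias")


class EmptyOutputError(ValueError):
    """QC removed every cell or every gene."""


class InsufficientDataError(ValueError):
    """Too few genes or cells to fit the requested model."""


@dataclass
class QCThresholds:
    min_umi: int = 1000          # strict >
    min_genes: int = 500         # strict >
    max_mito_frac: float = 0.15  # strict <
    min_cells_per_gene: int = 10  # inclusive >=
    max_umi: dict[str, float] | None = None    # per-donor caps, inclusive <=
    max_genes: dict[str, float] | None = None
    cap_quantile: float = 0.995  # per-donor default when caps not supplied

    def validate(self) -> None:
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")
        if self.max_umi is not None:
            for donor, cap in self.max_umi.items():
                if cap < self.min_umi:
                    raise ValueError(f"max_umi[{donor}] below min_umi")


def compute_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell total UMI, genes detected, and mitochondrial fraction.

    The mitochondrial fraction of an all-zero cell is defined as 0.
    """
    X = sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_mask = adata.var["mito"].values.astype(bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"total_umi": total, "n_genes": n_genes, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def filter_cells_genes(adata: ad.AnnData, thr: QCThresholds | None = None) -> ad.AnnData:
    """Apply cell QC then the gene detection filter, preserving input order.

    Cell bounds are strict (>) for the minima and the mito fraction (<);
    per-donor maxima are inclusive (<=) and default to the per-donor
    ``cap_quantile`` quantile when not supplied.  A per-donor filter
    report is logged and stored in ``.uns['qc_report']``.
    """
    thr = thr or QCThresholds()
    thr.validate()
    qc = compute_qc_metrics(adata)
    donors = adata.obs["donor"].astype(str) if "donor" in adata.obs else pd.Series(
        "all", index=adata.obs_names)

    total = qc["total_umi"].values
    n_detect = qc["n_genes"].values
    keep = ((total > thr.min_umi) & (n_detect > thr.min_genes)
            & (qc["mito_frac"].values < thr.max_mito_frac))
    report = []
    for donor in donors.unique():
        mask = (donors == donor).values
        cap_umi = (thr.max_umi or {}).get(donor)
        if cap_umi is None:
            cap_umi = float(np.quantile(total[mask], thr.cap_quantile))
        cap_genes = (thr.max_genes or {}).get(donor)
        if cap_genes is None:
            cap_genes = float(np.quantile(n_detect[mask], thr.cap_quantile))
        keep[mask] &= (total[mask] <= cap_umi) & (n_detect[mask] <= cap_genes)
        report.append({"donor": donor, "cells_in": int(mask.sum()),
                       "cells_kept": int(keep[mask].sum()),
                       "max_umi": cap_umi, "max_genes": cap_genes})
    if keep.sum() == 0:
        raise EmptyOutputError("no cells pass QC")

    out = adata[keep].copy()
    expressed = np.asarray((sp.csr_matrix(out.X) > 0).sum(axis=0)).ravel()
    gene_keep = expressed >= thr.min_cells_per_gene
    if gene_keep.sum() == 0:
        raise EmptyOutputError("no genes pass the detection filter")
    out = out[:, gene_keep].copy()
    out.uns["qc_report"] = pd.DataFrame(report)
    for row in report:
        log.info("qc donor=%s cells %d -> %d (max_umi=%.0f max_genes=%.0f)",
                 row["donor"], row["cells_in"], row["cells_kept"],
                 row["max_umi"], row["max_genes"])
    log.info("qc genes %d -> %d", adata.n_vars, out.n_vars)
    return out


def normalize_log(adata: ad.AnnData, scale_factor: float = 10000.0,
                  base: float = 2.0) -> ad.AnnData:
    """Library-size normalize to ``scale_factor`` per cell and log-transform.

    value = log_base(1 + count / cell_total * scale_factor).  Raw counts
    are kept in ``.layers['counts']``; zero counts map to zero.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run QC first")
    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(adata.X).copy()
    scaled = X.multiply(scale_factor / totals[:, None]).tocsr()
    scaled.data = np.log1p(scaled.data) / np.log(base)
    out.X = scaled
    out.uns["scale_factor"] = scale_factor
    out.uns["log_base"] = base
    return out


@dataclass
class HVGFit:
    """Per-gene CV^2-vs-mean statistics and the fitted technical trend
    CV^2(mu) = a1 / mu + alpha0."""

    table: pd.DataFrame
    a1: float
    alpha0: float
    mean_min: float
    disp_min: float
    n_iter: int

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def _fit_gamma_cv2(mu: np.ndarray, cv2: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[float, float, int]:
    """Gamma GLM with identity link of CV^2 on 1/mu, by IRLS.

    For the gamma family the variance is proportional to the squared
    mean, so each IRLS step is a weighted least squares with weights
    1/fitted^2.  Converges when the relative deviance change is < tol.
    """
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    beta = np.linalg.lstsq(X, cv2, rcond=None)[0]
    dev_old = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fitted = np.clip(X @ beta, 1e-12, None)
        w = 1.0 / fitted**2
        sw = np.sqrt(w)
        beta = np.linalg.lstsq(X * sw[:, None], cv2 * sw, rcond=None)[0]
        fitted = np.clip(X @ beta, 1e-12, None)
        ratio = np.clip(cv2 / fitted, 1e-12, None)
        dev = 2.0 * np.sum(-np.log(ratio) + ratio - 1.0)
        if abs(dev_old - dev) < tol * (abs(dev) + 1e-12):
            break
        dev_old = dev
    return float(beta[1]), float(beta[0]), n_iter


def select_hvgs(adata: ad.AnnData, mean_min: float = 0.05,
                disp_min: float = 0.05) -> HVGFit:
    """Select highly variable genes by excess CV^2 over the gamma-GLM trend.

    Statistics are computed on library-size-scaled (pre-log) values,
    where CV^2-vs-mean noise theory applies.  The dispersion score is
    observed CV^2 minus the fitted CV^2 at the gene's mean; a gene is
    selected when mean > ``mean_min`` and dispersion > ``disp_min``.
    """
    if adata.n_obs < 2:
        raise InsufficientDataError("need at least 2 cells")
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    sf = float(adata.uns.get("scale_factor", 10000.0))
    scaled = counts.multiply(sf / totals[:, None]).tocsr()
    mu = np.asarray(scaled.mean(axis=0)).ravel()
    ex2 = np.asarray(scaled.power(2).mean(axis=0)).ravel()
    var = (ex2 - mu**2) * adata.n_obs / max(adata.n_obs - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mu > 0, var / np.maximum(mu, 1e-300) ** 2, 0.0)
    cv2 = np.clip(cv2, 0.0, None)

    fit_mask = (mu > mean_min) & (cv2 > 0)
    if fit_mask.sum() < 10:
        raise InsufficientDataError(
            f"only {int(fit_mask.sum())} genes with mean > {mean_min}")
    a1, alpha0, n_iter = _fit_gamma_cv2(mu[fit_mask], cv2[fit_mask])
    with np.errstate(divide="ignore"):
        fitted = np.where(mu > 0, a1 / np.maximum(mu, 1e-300) + alpha0, np.inf)
    dispersion = cv2 - fitted
    selected = (mu > mean_min) & (dispersion > disp_min)
    table = pd.DataFrame(
        {"mean": mu, "cv2": cv2, "fitted_cv2": fitted,
         "dispersion": dispersion, "selected": selected},
        index=adata.var_names,
    )
    log.info("hvg: %d selected of %d genes (a1=%.4g alpha0=%.4g, %d IRLS iters)",
             int(selected.sum()), adata.n_vars, a1, alpha0, n_iter)
    return HVGFit(table=table, a1=a1, alpha0=alpha0,
                  mean_min=mean_min, disp_min=disp_min, n_iter=n_iter)


def remove_flagged_genes(genes, flagged=None, patterns=None) -> list[str]:
    """Drop ribosomal / mitochondrial / heat-shock genes from a gene list.

    ``flagged`` may be an explicit collection of gene ids; otherwise
    ``patterns`` (name prefixes) are matched.  The removal count is logged.
    """
    genes = list(genes)
    if flagged is not None:
        flagged = set(flagged)
        kept = [g for g in genes if g not in flagged]
    else:
        pats = tuple(patterns) if patterns is not None else ("MT-", "RPS", "RPL", "HSP")
        kept = [g for g in genes if not str(g).startswith(pats)]
    removed = len(genes) - len(kept)
    log.info("flagged-gene removal: %d of %d removed, %d retained",
             removed, len(genes), len(kept))
    if not kept:
        warnings.warn("all genes were flagged; returning an empty list")
    return kept


def regress_batch(X: np.ndarray, batch: np.ndarray, conv: float = 1e-4) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch adjustment.

    ``X`` is genes x cells (dense, log scale); ``batch`` labels one batch
    per cell.  Per-gene values are standardized against the
    batch-size-weighted grand mean and pooled variance; per-batch
    additive and multiplicative effects are shrunk toward common priors
    (normal for location, inverse-gamma for scale) by the standard
    parametric empirical-Bayes fixed-point iteration, then removed and
    the matrix back-transformed.  Genes with zero pooled variance are
    returned unchanged.  A single batch is an identity (with a warning);
    a batch with one cell is an error naming the batch.
    """
    X = np.asarray(X, dtype=np.float64)
    batch = np.asarray(batch)
    levels, inv = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    n_genes, n_cells = X.shape
    if n_batch == 1:
        warnings.warn("single batch: batch adjustment is an identity")
        return X.copy()
    counts = np.bincount(inv, minlength=n_batch)
    for lev, c in zip(levels, counts):
        if c < 2:
            raise ValueError(f"batch {lev!r} has fewer than 2 cells")

    design = np.zeros((n_cells, n_batch))
    design[np.arange(n_cells), inv] = 1.0
    B_hat = np.linalg.solve(design.T @ design, design.T @ X.T)  # batch x genes
    grand_mean = (counts / n_cells) @ B_hat
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2) @ np.full(n_cells, 1.0 / n_cells)

    ok = var_pooled > 0
    stand_sd = np.sqrt(var_pooled, where=ok, out=np.ones_like(var_pooled))
    s_data = (X - grand_mean[:, None]) / stand_sd[:, None]

    gamma_hat = np.linalg.solve(design.T @ design, design.T @ s_data.T)  # batch x genes
    delta_hat = np.stack([s_data[:, inv == b].var(axis=1, ddof=1) for b in range(n_batch)])

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1)  # population variance of per-gene location effects

    def aprior(d):
        m, s2 = d.mean(), d.var(ddof=1)
        return (2.0 * s2 + m**2) / s2

    def bprior(d):
        m, s2 = d.mean(), d.var(ddof=1)
        return (m * s2 + m**3) / s2

    bayes = s_data.copy()
    for b in range(n_batch):
        idx = inv == b
        n_b = counts[b]
        a, bp = aprior(delta_hat[b]), bprior(delta_hat[b])
        g_old, d_old = gamma_hat[b].copy(), delta_hat[b].copy()
        sd_b = s_data[:, idx]
        change = 1.0
        while change > conv:
            g_new = (t2[b] * n_b * gamma_hat[b] + d_old * gamma_bar[b]) / (
                t2[b] * n_b + d_old)
            sum2 = ((sd_b - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + bp) / (n_b / 2.0 + a - 1.0)
            # signed denominators, matching the reference iteration exactly
            change = max(np.max(np.abs(g_new - g_old) / g_old),
                         np.max(np.abs(d_new - d_old) / d_old))
            g_old, d_old = g_new, d_new
        bayes[:, idx] = (sd_b - g_old[:, None]) / np.sqrt(d_old)[:, None]

    out = bayes * stand_sd[:, None] + grand_mean[:, None]
    out[~ok] = X[~ok]
    return out
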