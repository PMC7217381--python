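"""Down-sampling, cluster composition, per-donor signature proportions.

Group composition is exact integer bookkeeping over cluster x donor-type
tables.  Signature proportions are computed per donor (the donor, not
the cell, is the independent unit), summarized as group means with
ranges and a case/control fold-difference, and compared across groups
by a donor-level Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("mkbias")


def downsample_group(adata: ad.AnnData, group_col: str, group: str,
                     target_n: int, seed: int = 0) -> ad.AnnData:
    """Uniformly subsample one group's cells (without replacement) to
    ``target_n``; other groups are untouched; cell order is preserved."""
    mask = (adata.obs[group_col].astype(str) == group).values
    n_group = int(mask.sum())
    if target_n > n_group:
        raise ValueError(f"target_n={target_n} exceeds group size {n_group}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.where(mask)[0], size=target_n, replace=False)
    keep = ~mask
    keep[chosen] = True
    log.info("downsample %s=%s: %d -> %d cells", group_col, group, n_group, target_n)
    return adata[keep].copy()


def cluster_composition(clusters, donor_type, donor_ids=None) -> pd.DataFrame:
    """Per-cluster cell counts and row-normalized percentages per donor
    type, with an optional per-donor breakdown in ``.attrs``."""
    clusters = np.asarray(clusters)
    donor_type = np.asarray(donor_type)
    if len(clusters) != len(donor_type):
        raise ValueError("labels are not aligned")
    tab = pd.crosstab(pd.Series(clusters, name="cluster"),
                      pd.Series(donor_type, name="donor_type"))
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    out = pd.concat({"count": tab, "pct": pct}, axis=1)
    if donor_ids is not None:
        out.attrs["per_donor"] = pd.crosstab(
            pd.Series(clusters, name="cluster"),
            pd.Series(np.asarray(donor_ids), name="donor"))
    return out


@dataclass
class ProportionSummary:
    per_donor: pd.DataFrame
    case_mean: float
    case_range: tuple[float, float]
    control_mean: float
    control_range: tuple[float, float]
    fold: float
    fold_rounded: int | None
    p_value: float


def signature_proportions(labels, donor_ids, donor_types,
                          target: str = "megakaryocyte") -> ProportionSummary:
    """Per-donor fraction of cells carrying the target lineage label, with
    group means, ranges, case/control fold, and a donor-level Wilcoxon
    rank-sum p-value."""
    df = pd.DataFrame({"label": np.asarray(labels),
                       "donor": np.asarray(donor_ids),
                       "group": np.asarray(donor_types)})
    if (df.groupby("donor").size() < 1).any():
        raise ValueError("every donor needs at least one cell")
    per_donor = df.groupby(["donor", "group"], observed=True).apply(
        lambda d: (d["label"] == target).mean(), include_groups=False
    ).rename("fraction").reset_index()
    case = per_donor.loc[per_donor["group"] == "case", "fraction"].values
    control = per_donor.loc[per_donor["group"] == "control", "fraction"].values
    case_mean, control_mean = float(case.mean()), float(control.mean())
    if control_mean == 0:
        warnings.warn("control mean is 0; fold reported as infinite")
        fold = float("inf")
        fold_rounded = None
    else:
        fold = case_mean / control_mean
        fold_rounded = int(round(fold))
    p = float(stats.mannwhitneyu(case, control, alternative="two-sided").pvalue)
    return ProportionSummary(
        per_donor=per_donor,
        case_mean=case_mean, case_range=(float(case.min()), float(case.max())),
        control_mean=control_mean,
        control_range=(float(control.min()), float(control.max())),
        fold=fold, fold_rounded=fold_rounded, p_value=p,
    )


def yates_chisq_2x2(table) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    statistic = sum((|O - E| - 0.5)^2 / E) with the correction capped so
    |O - E| - 0.5 >= 0; p from chi-square with 1 df.  All margins must
    be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative entries")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))
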