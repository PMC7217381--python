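"""Synthetic HSPC cohorts with planted ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: negative-binomial UMI counts with per-cell library-size
variation, multiplicative per-donor batch effects, branching lineage
programs activated linearly along a latent pseudotime (HSC root with
erythroid / megakaryocyte / myeloid / lymphoid branches), an expanded
megakaryocyte-progenitor branch in the disease group, genotype-linked
up-regulation of designated genes in mutant cells, a contaminant
(pDC-like) cluster, and low-UMI / high-mitochondrial cells so the QC
filter has true positives.  Every planted quantity is returned as a
:class:`SyntheticTruth` record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


class ParameterError(ValueError):
    """Raised when cohort parameters violate their invariants."""


LINEAGES = ("erythroid", "megakaryocyte", "myeloid", "lymphoid")


@dataclass
class GenotypeBlock:
    """Genotype structure for case cells and the plate-style dataset.

    ``marker_freqs`` are the expressing frequencies of the designated
    megakaryocyte-restricted surface-receptor gene (a G6B-like marker) in
    the three genotype groups of the plate-style dataset; the defaults
    reproduce the frequencies reported for MPIG6B (14.7% in healthy-donor
    wild-type cells, 22.9% in patient wild-type cells, 32% in mutant
    cells).  ``group_sizes`` default to the study's group sizes
    (678 / 388 / 1,668 cells, 2,734 in total).
    """

    mutant_fraction: float = 0.8
    effect_log2fc: float = 1.5
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"WT-HD": 678, "WT-patient": 388, "mutant": 1668}
    )
    marker_freqs: dict[str, float] = field(
        default_factory=lambda: {"WT-HD": 0.147, "WT-patient": 0.229, "mutant": 0.32}
    )
    marker_level_log2fc: float = 1.0


@dataclass
class CohortParams:
    """Parameters of a synthetic two-group (case / control) HSPC cohort.

    Defaults mirror the study design at reduced scale: 15 myelofibrosis
    donors vs 6 controls, megakaryocyte-branch fractions 4.98% (case) vs
    0.44% (control), and lineage programs strong enough that every
    downstream stage has signal to recover.
    """

    n_donors_case: int = 15
    n_donors_control: int = 6
    cells_per_donor: int = 300
    n_genes: int = 1000
    n_mito_genes: int = 10
    program_size: int = 20
    program_log2fc: float = 4.0
    mkp_fraction_case: float = 0.0498
    mkp_fraction_control: float = 0.0044
    branch_proportions: dict[str, dict[str, float]] | None = None
    batch_effect_sd: float = 0.15
    nb_dispersion: float = 0.2
    activation_saturation: float = 0.6  # pseudotime at which a branch program is fully on
    libsize_log_mu: float = 0.0
    libsize_log_sd: float = 0.3
    mean_total_umi: float = 3000.0
    contaminant_fraction: float = 0.02
    lowq_fraction: float = 0.02
    genotype: GenotypeBlock = field(default_factory=GenotypeBlock)
    seed: int = 0

    def resolved_branch_proportions(self) -> dict[str, dict[str, float]]:
        if self.branch_proportions is not None:
            return self.branch_proportions
        props = {}
        for group, mk in (("case", self.mkp_fraction_case), ("control", self.mkp_fraction_control)):
            lymph = 0.05 if group == "case" else 0.15
            base = {"erythroid": 0.25, "megakaryocyte": mk, "myeloid": 0.25, "lymphoid": lymph}
            base["uncommitted"] = 1.0 - sum(base.values())
            props[group] = base
        return props

    def validate(self) -> None:
        for name in ("n_donors_case", "n_donors_control", "cells_per_donor", "n_genes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ParameterError("n_mito_genes must be in [0, n_genes)")
        for name in ("mkp_fraction_case", "mkp_fraction_control", "contaminant_fraction",
                     "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.genotype.mutant_fraction <= 1.0:
            raise ParameterError("mutant_fraction must be in [0, 1]")
        for group, props in self.resolved_branch_proportions().items():
            if any(p < 0 for p in props.values()):
                raise ParameterError(f"negative branch proportion for {group}")
            if sum(props.values()) > 1.0 + 1e-9:
                raise ParameterError(f"branch proportions for {group} sum to > 1")
        for v in (self.program_log2fc, self.batch_effect_sd, self.nb_dispersion):
            if not np.isfinite(v):
                raise ParameterError("effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per generated cell plus the planted
    gene sets, batch factors and effect sizes used as oracles in tests."""

    cells: pd.DataFrame
    programs: dict[str, np.ndarray]
    program_log2fc: float
    genotype_effect_genes: dict[int, float]
    batch_factors: pd.DataFrame
    marker_gene: int | None = None
    marker_freqs: dict[str, float] | None = None


def _gene_annotations(params: CohortParams) -> pd.DataFrame:
    """Gene ids with mitochondrial / ribosomal / heat-shock naming so that
    pattern-based flagging has true positives."""
    names = [f"G{i:05d}" for i in range(params.n_genes)]
    for j in range(params.n_mito_genes):
        names[params.n_genes - params.n_mito_genes + j] = f"MT-{j}"
    # a handful of ribosomal / heat-shock genes among the background
    specials = ["RPS-A", "RPS-B", "RPL-A", "RPL-B", "HSP-A", "HSP-B"]
    base = params.n_genes - params.n_mito_genes - len(specials)
    for j, s in enumerate(specials):
        names[base + j] = s
    var = pd.DataFrame(index=pd.Index(names, name="gene_id"))
    var["gene_name"] = names
    return var


def _default_programs(params: CohortParams) -> dict[str, np.ndarray]:
    """Disjoint marker-gene blocks at the front of the gene index for the
    HSC root program, each lineage branch and the pDC-like contaminant."""
    size = params.program_size
    blocks = ["hsc", *LINEAGES, "pdc"]
    needed = size * len(blocks)
    if needed > params.n_genes - params.n_mito_genes - 6:
        raise ParameterError("n_genes too small for the default lineage programs")
    return {name: np.arange(i * size, (i + 1) * size) for i, name in enumerate(blocks)}


def generate_cohort(params: CohortParams) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a case/control cohort of negative-binomial UMI counts.

    Returns the counts as cells x genes AnnData (obs: donor, group,
    genotype; var: gene flags) and the :class:`SyntheticTruth` oracle.
    Identical parameters and seed give byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    var = _gene_annotations(params)
    programs = _default_programs(params)
    props = params.resolved_branch_proportions()

    # baseline gene abundances: log-normal, mitochondrial genes pinned to
    # ~5% of the library so the QC mito fraction has a realistic baseline
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    mito = np.zeros(n_genes, dtype=bool)
    mito[n_genes - params.n_mito_genes:] = True
    # lineage-program genes share a characteristic baseline (markers are
    # moderately expressed when off, dominant when the program is on)
    all_prog = np.concatenate(list(programs.values()))
    base[all_prog] = np.median(base[~mito])
    base[mito] = base[mito] / base[mito].sum() * 0.05
    base[~mito] = base[~mito] / base[~mito].sum() * 0.95
    base *= params.mean_total_umi

    donors = [(f"MF{i + 1:02d}", "case") for i in range(params.n_donors_case)]
    donors += [(f"HC{i + 1:02d}", "control") for i in range(params.n_donors_control)]

    batch = {d: np.exp(rng.normal(0.0, params.batch_effect_sd, size=n_genes)) for d, _ in donors}

    effect_genes = {}
    if params.genotype.effect_log2fc:
        # designated genotype-responsive genes: first genes of the Mk program,
        # i.e. megakaryocyte-restricted markers aberrantly up in the clone
        for g in programs["megakaryocyte"][:5]:
            effect_genes[int(g)] = params.genotype.effect_log2fc

    blocks, meta_rows = [], []
    branch_names = list(props["case"].keys())
    for donor, group in donors:
        n = params.cells_per_donor
        p = np.array([props[group][b] for b in branch_names], dtype=float)
        branch_idx = rng.choice(len(branch_names), size=n, p=p / p.sum())
        branch = np.array(branch_names, dtype=object)[branch_idx]
        t = rng.uniform(0.0, 1.0, size=n)
        t[branch == "uncommitted"] *= 0.3
        contaminant = rng.random(n) < params.contaminant_fraction
        eligible = ~contaminant
        lowq = np.zeros(n, dtype=bool)
        lowq[eligible] = rng.random(eligible.sum()) < params.lowq_fraction
        if group == "case":
            genotype = np.where(rng.random(n) < params.genotype.mutant_fraction,
                                "mutant", "WT-patient")
        else:
            genotype = np.full(n, "WT-HD", dtype=object)
        lib = np.exp(rng.normal(params.libsize_log_mu, params.libsize_log_sd, size=n))

        mean = np.tile(base * batch[donor], (n, 1)) * lib[:, None]
        # HSC root program fades as pseudotime advances; branch programs
        # ramp linearly and saturate at activation_saturation
        sat = max(params.activation_saturation, 1e-9)
        act = np.clip(t / sat, 0.0, 1.0)
        act_root = 1.0 - act
        act_root[contaminant] = 0.0
        mean[:, programs["hsc"]] *= 2.0 ** (params.program_log2fc * act_root[:, None])
        for lin in LINEAGES:
            on_branch = (branch == lin) & ~contaminant
            if on_branch.any():
                mean[np.ix_(on_branch, programs[lin])] *= (
                    2.0 ** (params.program_log2fc * act[on_branch, None]))
        if contaminant.any():
            mean[np.ix_(contaminant, programs["pdc"])] *= 2.0 ** params.program_log2fc
        is_mut = genotype == "mutant"
        if is_mut.any():
            for g, lfc in effect_genes.items():
                mean[is_mut, g] *= 2.0 ** lfc
        if lowq.any():
            # dying/empty-droplet cells: a few hundred UMIs with the
            # mitochondrial share inflated well past the QC cutoff
            targets = rng.uniform(200.0, 600.0, size=int(lowq.sum()))
            rows = np.where(lowq)[0]
            mean[rows] *= (targets / mean[rows].sum(axis=1))[:, None]
            mean[np.ix_(rows, mito)] *= 10.0

        r = 1.0 / params.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int32)
        blocks.append(sp.csr_matrix(counts))
        branch_out = branch.copy()
        branch_out[contaminant] = "pDC"
        meta_rows.append(pd.DataFrame({
            "donor": donor, "group": group, "genotype": genotype,
            "branch": branch_out, "pseudotime": t,
            "contaminant": contaminant, "lowq": lowq,
        }))

    X = sp.vstack(blocks, format="csr")
    meta = pd.concat(meta_rows, ignore_index=True)
    meta.index = pd.Index([f"CELL{i:06d}" for i in range(len(meta))], name="barcode")
    obs = meta[["donor", "group", "genotype"]].copy()
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())
    adata.var["mito"] = mito
    from .io import annotate_gene_flags

    annotate_gene_flags(adata)
    adata.var["mito"] = mito  # explicit planted flag wins over name pattern

    truth = SyntheticTruth(
        cells=meta,
        programs=programs,
        program_log2fc=params.program_log2fc,
        genotype_effect_genes=effect_genes,
        batch_factors=pd.DataFrame(batch, index=var.index),
    )
    return adata, truth


def generate_genotyped_cells(params: CohortParams) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a plate-style genotyped dataset (WT-HD / WT-patient / mutant).

    Group sizes are exact; the designated G6B-like marker gene is expressed
    with the configured per-group frequency (Bernoulli detection) and, when
    detected, at a level elevated in mutant cells by
    ``marker_level_log2fc``.  Background genes are shared negative-binomial
    noise so level tests have a realistic null.
    """
    params.validate()
    gb = params.genotype
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    var = _gene_annotations(params)
    marker_gene = 0  # by convention the first gene is the G6B-like marker

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = base / base.sum() * params.mean_total_umi

    groups, sizes = list(gb.group_sizes.keys()), list(gb.group_sizes.values())
    labels = np.repeat(groups, sizes)
    n = len(labels)
    lib = np.exp(rng.normal(params.libsize_log_mu, params.libsize_log_sd, size=n))
    mean = np.outer(lib, base)
    r = 1.0 / params.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int32)

    marker_base_level = 3.0
    for g in groups:
        mask = labels == g
        freq = gb.marker_freqs[g]
        if not 0.0 <= freq <= 1.0:
            raise ParameterError(f"marker frequency for {g} outside [0, 1]")
        detected = rng.random(mask.sum()) < freq
        lam = marker_base_level * (2.0 ** gb.marker_level_log2fc if g == "mutant" else 1.0)
        level = 1 + rng.poisson(lam, size=mask.sum())
        counts[mask, marker_gene] = np.where(detected, level, 0)

    meta = pd.DataFrame({"donor": "plate", "group": np.where(labels == "WT-HD", "control", "case"),
                         "genotype": labels})
    meta.index = pd.Index([f"PLATE{i:05d}" for i in range(n)], name="barcode")
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=meta, var=var.copy())
    from .io import annotate_gene_flags

    annotate_gene_flags(adata)

    cells = meta.copy()
    cells["branch"] = "uncommitted"
    cells["pseudotime"] = 0.0
    cells["contaminant"] = False
    cells["lowq"] = False
    truth = SyntheticTruth(
        cells=cells,
        programs={},
        program_log2fc=0.0,
        genotype_effect_genes={marker_gene: gb.marker_level_log2fc},
        batch_factors=pd.DataFrame(index=var.index),
        marker_gene=marker_gene,
        marker_freqs=dict(gb.marker_freqs),
    )
    return adata, truth
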