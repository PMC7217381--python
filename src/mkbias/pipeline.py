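"""End-to-end pipeline: QC -> normalize -> HVG -> batch -> cluster ->
contaminant removal -> re-cluster -> signatures -> composition -> MkP
gate -> markers -> genotype tests -> trajectory -> GSEA.

Each stage writes a TSV (with a provenance header naming the package
version, config hash and seed) into the run directory and logs one
structured line with its cell/gene counts.  Re-running with the same
config and inputs reproduces byte-identical outputs.  Input files are
never mutated.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import cluster as cl
from . import composition as comp
from . import diffex, enrichment, preprocess, signatures, simulate, trajectory
from .config import RunConfig
from .io import hash_config, read_geneset_tsv, read_gmt, read_mtx_triplet, write_table

log = logging.getLogger("mkbias")

LINEAGE_KEYS = ("hsc", "erythroid", "megakaryocyte", "myeloid", "lymphoid", "pdc")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _default_inputs(config: RunConfig) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Simulate a cohort and derive gene sets from the planted programs."""
    params = simulate.CohortParams(
        n_donors_case=4, n_donors_control=3,
        cells_per_donor=config.sim_cells_per_donor,
        n_genes=config.sim_n_genes, seed=config.seed,
        mkp_fraction_case=0.15, mkp_fraction_control=0.01,
    )
    adata, truth = simulate.generate_cohort(params)
    gene_sets = {key: [adata.var_names[i] for i in truth.programs[prog]]
                 for key, prog in zip(LINEAGE_KEYS, ("hsc", *simulate.LINEAGES, "pdc"))}
    adata.uns["truth_cells"] = truth.cells
    return adata, gene_sets


def _load_gene_sets(path: str) -> dict[str, list[str]]:
    if path.endswith(".gmt"):
        return read_gmt(path)
    return read_geneset_tsv(path)


def _cluster_stage(norm: ad.AnnData, hvg_genes: list[str], config: RunConfig):
    sub = norm[:, hvg_genes]
    X = np.asarray(sp.csr_matrix(sub.X).todense())
    batches = norm.obs["donor"].astype(str).values
    adjusted = preprocess.regress_batch(X.T, batches).T
    emb = cl.run_pca(adjusted, n_components=min(config.n_pcs_max, adjusted.shape[0] - 1))
    n_pcs = cl.choose_n_pcs(emb.variances, override=config.n_pcs)
    coords = emb.coords[:, :n_pcs]
    graph = cl.build_snn_graph(coords, k=min(config.neighbors, coords.shape[0] - 1))
    assign = cl.louvain_cluster(graph, seed=config.seed, resolution=config.resolution)
    return adjusted, emb, coords, graph, assign


def run_pipeline(config: RunConfig, adata: ad.AnnData | None = None,
                 gene_sets: dict[str, list[str]] | None = None) -> Path:
    """Execute every stage on the given (or simulated) count matrix.

    Returns the run directory.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = hash_config(config.param_dict())
    seed = config.seed
    kw = {"seed": seed, "config_hash": chash}

    if adata is None:
        if config.input_dir is not None:
            adata = read_mtx_triplet(config.input_dir, cell_meta=config.cell_meta)
        else:
            adata, sim_sets = _default_inputs(config)
            gene_sets = gene_sets or sim_sets
    if gene_sets is None:
        if config.geneset_file is None:
            raise StageError("inputs", ValueError("no gene sets supplied"))
        gene_sets = _load_gene_sets(config.geneset_file)

    stage = "qc"
    try:
        thr = preprocess.QCThresholds(
            min_umi=config.min_umi, min_genes=config.min_genes,
            max_mito_frac=config.max_mito,
            min_cells_per_gene=config.min_cells_per_gene)
        filtered = preprocess.filter_cells_genes(adata, thr)
        write_table(filtered.uns["qc_report"], out / "qc_report.tsv", **kw)
        log.info("stage=qc cells %d -> %d genes %d -> %d",
                 adata.n_obs, filtered.n_obs, adata.n_vars, filtered.n_vars)

        stage = "normalize"
        norm = preprocess.normalize_log(filtered, scale_factor=config.scale_factor)

        stage = "hvg"
        hvg = preprocess.select_hvgs(norm, mean_min=config.mean_min,
                                     disp_min=config.disp_min)
        hvg_genes = preprocess.remove_flagged_genes(list(hvg.selected))
        write_table(hvg.table.reset_index(), out / "hvg.tsv", **kw)
        log.info("stage=hvg %d selected, %d after flagged-gene removal",
                 len(hvg.selected), len(hvg_genes))
        if len(hvg_genes) < 2:
            raise ValueError("fewer than 2 highly variable genes retained")

        stage = "cluster"
        _, emb, coords, graph, assign = _cluster_stage(norm, hvg_genes, config)

        stage = "contaminant"
        pdc_set = signatures.GeneSet("pdc", gene_sets["pdc"]) if "pdc" in gene_sets else None
        removed: list[int] = []
        if pdc_set is not None:
            pdc_score = signatures.score_geneset_mean(norm, pdc_set)
            thr_pdc = config.contaminant_threshold
            if thr_pdc is None:
                vals = pdc_score.values.values
                thr_pdc = float(vals.mean() + 3.0 * vals.std())
            norm2, removed = signatures.flag_contaminant_cluster(
                norm, assign.labels, pdc_score, thr_pdc)
        else:
            norm2 = norm
        log.info("stage=contaminant removed clusters %s, cells %d -> %d",
                 removed, norm.n_obs, norm2.n_obs)

        stage = "recluster"
        if removed:
            _, emb, coords, graph, assign = _cluster_stage(norm2, hvg_genes, config)
        clusters = pd.DataFrame({"barcode": norm2.obs_names,
                                 "cluster": assign.labels,
                                 "modularity": assign.modularity})
        write_table(clusters, out / "clusters.tsv", **kw)

        if config.embed:
            stage = "embedding"
            layout = cl.embed_2d(coords, method="umap", seed=seed)
            write_table(pd.DataFrame({"barcode": norm2.obs_names,
                                      "umap1": layout[:, 0], "umap2": layout[:, 1]}),
                        out / "umap.tsv", **kw)

        stage = "signatures"
        lineage_sets = {k: signatures.GeneSet(k, gene_sets[k])
                        for k in ("erythroid", "megakaryocyte", "myeloid", "lymphoid")
                        if k in gene_sets}
        scores = {k: signatures.score_geneset_mean(norm2, gs)
                  for k, gs in lineage_sets.items()}
        control_mask = (norm2.obs["group"].astype(str) == "control").values
        if not control_mask.any():
            control_mask = np.ones(norm2.n_obs, dtype=bool)
        thresholds = signatures.default_lineage_thresholds(
            scores, control_mask, quantile=config.lineage_quantile)
        lineage = signatures.assign_lineage(scores, thresholds)
        score_df = pd.DataFrame({k: v.values for k, v in scores.items()})
        score_df.insert(0, "barcode", norm2.obs_names)
        score_df["lineage"] = lineage.values
        write_table(score_df, out / "lineage_scores.tsv", **kw)

        stage = "composition"
        donor_type = norm2.obs["group"].astype(str).values
        donors = norm2.obs["donor"].astype(str).values
        tab = comp.cluster_composition(assign.labels, donor_type, donors)
        write_table(tab.reset_index(), out / "composition.tsv", **kw)
        n_control = int((donor_type == "control").sum())
        if 0 < n_control < int((donor_type == "case").sum()):
            ds = comp.downsample_group(norm2, "group", "case", n_control, seed=seed)
            ds_mask = norm2.obs_names.isin(ds.obs_names)
            tab_ds = comp.cluster_composition(
                assign.labels[ds_mask], donor_type[ds_mask])
            write_table(tab_ds.reset_index(), out / "composition_downsampled.tsv", **kw)
        props = comp.signature_proportions(lineage.values, donors, donor_type)
        write_table(props.per_donor, out / "proportions.tsv", **kw)
        log.info("stage=composition mk %.4f (case) vs %.4f (control), fold %s p=%.3g",
                 props.case_mean, props.control_mean, props.fold_rounded, props.p_value)

        stage = "mkp_gate"
        mk_set = lineage_sets.get("megakaryocyte")
        gated_idx = pd.Index([])
        if mk_set is not None:
            auc = signatures.aucell_score(norm2, mk_set,
                                          top_frac=config.auc_top_frac, seed=seed)
            gated_idx, _ = signatures.gate_cells_by_score(auc, threshold=config.auc_gate)
            gate_df = pd.DataFrame({"barcode": norm2.obs_names,
                                    "auc": auc.values.values,
                                    "gated": norm2.obs_names.isin(gated_idx)})
            write_table(gate_df, out / "mkp_gate.tsv", **kw)

        stage = "markers"
        markers = diffex.cluster_markers(
            norm2, assign.labels, lfc_min=config.lfc_min, q_max=config.q_max,
            frac_min=config.frac_min, top_n=config.top_n)
        write_table(markers[markers["reported_marker"]], out / "markers.tsv", **kw)

        stage = "genotype"
        if "genotype" in norm2.obs and norm2.obs["genotype"].nunique() >= 2:
            rows = []
            for gene in (mk_set.genes if mk_set else [])[:5]:
                if gene in norm2.var_names:
                    rows.append(diffex.genotype_expression_test(
                        norm2, norm2.obs["genotype"].values, gene))
            if rows:
                write_table(pd.concat(rows, ignore_index=True),
                            out / "genotype_tests.tsv", **kw)
        else:
            log.info("stage=genotype skipped: no genotype column with >= 2 groups")

        stage = "trajectory"
        k_traj = min(config.traj_k, norm2.n_obs - 2)
        dmap = trajectory.diffusion_map(coords, k=k_traj)
        hsc_scores = (signatures.score_geneset_mean(
            norm2, signatures.GeneSet("hsc", gene_sets["hsc"])).values.values
            if "hsc" in gene_sets else -assign.labels.astype(float))
        pt = trajectory.pseudotime_from_root(dmap, root_scores=hsc_scores)
        write_table(pd.DataFrame({"barcode": norm2.obs_names,
                                  "pseudotime": pt.pseudotime}),
                    out / "pseudotime.tsv", **kw)
        # path = clusters ordered by mean pseudotime from the root cluster
        # toward the megakaryocyte-program extreme
        mk_scores = scores.get("megakaryocyte")
        if mk_scores is not None:
            cmean = pd.DataFrame({"cluster": assign.labels,
                                  "pt": pt.pseudotime,
                                  "mk": mk_scores.values.values}).groupby("cluster").mean()
            root_cluster = int(assign.labels[pt.root])
            mk_cluster = int(cmean["mk"].idxmax())
            path = [root_cluster] + ([mk_cluster] if mk_cluster != root_cluster else [])
            Xn = np.asarray(sp.csr_matrix(norm2.X).todense())
            finite = np.isfinite(pt.pseudotime)
            profiles = trajectory.path_profile(
                Xn[finite], pt.pseudotime[finite], assign.labels[finite], path,
                n_avg=min(config.n_avg, int(np.isin(assign.labels[finite], path).sum())))
            profiles.index = norm2.var_names
            write_table(profiles.iloc[:, :: max(1, profiles.shape[1] // 200)]
                        .reset_index(), out / "path_profiles.tsv", **kw)
            trends = trajectory.rank_trend_genes(
                Xn[finite], pt.pseudotime[finite],
                list(norm2.var_names), norm2.var_names)
            write_table(trends, out / "trend_genes.tsv", **kw)

        stage = "gsea"
        case_mask = (norm2.obs["group"].astype(str) == "case").values
        gated_mask = norm2.obs_names.isin(gated_idx)
        de_mask = gated_mask if (gated_mask & case_mask).sum() >= 3 and (
            gated_mask & ~case_mask).sum() >= 3 else np.ones(norm2.n_obs, bool)
        sub = norm2[de_mask]
        Xs = np.asarray(sp.csr_matrix(sub.X).todense())
        expressing = np.asarray((sp.csr_matrix(sub.layers["counts"]) > 0).todense())
        de = diffex._group_stats(Xs, expressing,
                                 (sub.obs["group"].astype(str) == "case").values)
        de.insert(0, "gene", sub.var_names)
        ranking = enrichment.rank_genes(de)
        gsea = enrichment.preranked_gsea(
            ranking, gene_sets, n_perm=config.n_perm, seed=seed,
            min_size=config.min_set_size, max_size=config.max_set_size)
        write_table(gsea, out / "gsea.tsv", **kw)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - halt with the stage name
        raise StageError(stage, err) from err
    log.info("pipeline complete: %s", out)
    return out
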