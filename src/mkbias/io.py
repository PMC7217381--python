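"""Readers and writers for the 10x-style MTX triplet and TSV tables.

All on-disk formats are plain text: MatrixMarket integer coordinate
matrices (genes x cells, 10x orientation), tab-separated feature/barcode
files, tab-separated metadata, GMT / two-column TSV gene sets.  The
in-memory container is :class:`anndata.AnnData` with cells as
observations and genes as variables.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger("mkbias")

MITO_PREFIX = "MT-"
FLAGGED_PATTERNS = ("MT-", "RPS", "RPL", "HSP")


def read_mtx_triplet(directory: str | Path, cell_meta: str | Path | None = None) -> ad.AnnData:
    """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv).

    The matrix file is genes x cells; the returned AnnData is cells x genes
    (CSR).  ``cell_meta``, if given, is a TSV with a ``barcode`` column that
    is joined onto ``.obs``.
    """
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene_id"))
    if features.shape[1] > 1:
        var["gene_name"] = features[1].astype(str).values
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="barcode"))
    X = sp.csr_matrix(mat.T)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    annotate_gene_flags(adata)
    if cell_meta is not None:
        meta = pd.read_csv(cell_meta, sep="\t")
        meta = meta.set_index("barcode")
        adata.obs = adata.obs.join(meta, how="left")
    return adata


def write_mtx_triplet(adata: ad.AnnData, directory: str | Path) -> None:
    """Write ``adata`` as a genes x cells integer MatrixMarket triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), X, field="integer")
    features = pd.DataFrame({"gene_id": adata.var_names})
    if "gene_name" in adata.var:
        features["gene_name"] = adata.var["gene_name"].values
    features.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    if len(adata.obs.columns):
        meta = adata.obs.reset_index(names="barcode")
        meta.to_csv(directory / "cell_meta.tsv", sep="\t", index=False)


def annotate_gene_flags(adata: ad.AnnData) -> None:
    """Add boolean mitochondrial and ribosomal/heat-shock flags to ``.var``."""
    names = adata.var["gene_name"] if "gene_name" in adata.var else adata.var_names.to_series()
    names = names.astype(str)
    adata.var["mito"] = names.str.startswith(MITO_PREFIX).values
    flagged = np.zeros(adata.n_vars, dtype=bool)
    for pat in FLAGGED_PATTERNS:
        flagged |= names.str.startswith(pat).values
    adata.var["flagged"] = flagged


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, name, description, then genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_geneset_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV gene-set file (set name, gene id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["set", "gene"])
    return {name: grp["gene"].astype(str).tolist() for name, grp in df.groupby("set", sort=False)}


def table_header(seed: int | None = None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"# mkbias v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                config_hash: str | None = None, index: bool = False) -> None:
    """Write a TSV with a provenance comment line naming version/config/seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(table_header(seed=seed, config_hash=config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def hash_config(mapping: dict) -> str:
    payload = repr(sorted((str(k), str(v)) for k, v in mapping.items()))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
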