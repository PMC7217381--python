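import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mkbias import preprocess, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A 2x2-donor cohort, 500 cells/donor, 1000 genes: the standard
    dimension-contract fixture."""
    params = simulate.CohortParams(
        n_donors_case=2, n_donors_control=2, cells_per_donor=500,
        n_genes=1000, seed=11)
    return simulate.generate_cohort(params)


@pytest.fixture(scope="session")
def norm_cohort(small_cohort):
    adata, truth = small_cohort
    filtered = preprocess.filter_cells_genes(adata)
    norm = preprocess.normalize_log(filtered)
    kept_truth = truth.cells.loc[norm.obs_names]
    return norm, truth, kept_truth


def make_adata(counts, gene_names=None, mito=None, obs=None):
    """Small dense-count AnnData builder for hand-constructed examples."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene_id"))
    var["gene_name"] = gene_names
    var["mito"] = np.zeros(n_genes, bool) if mito is None else np.asarray(mito, bool)
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    return adata
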