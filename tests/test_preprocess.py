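"""QC, normalization, HVG selection and batch-adjustment behavior."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mkbias import preprocess, simulate
from mkbias.preprocess import (
    EmptyOutputError,
    InsufficientDataError,
    QCThresholds,
    _fit_gamma_cv2,
)

from conftest import make_adata


class TestQCMetrics:
    def test_single_mito_gene_cell(self):
        adata = make_adata([[5, 0]], mito=[True, False])
        qc = preprocess.compute_qc_metrics(adata)
        assert qc.iloc[0].tolist() == [5, 1, 1.0]

    def test_all_zero_cell_convention(self):
        adata = make_adata([[0, 0], [1, 2]], mito=[True, False])
        qc = preprocess.compute_qc_metrics(adata)
        assert qc.iloc[0].tolist() == [0, 0, 0.0]

    def test_planted_lowq_cells_have_lowest_umi(self, small_cohort):
        adata, truth = small_cohort
        qc = preprocess.compute_qc_metrics(adata)
        lowq = truth.cells["lowq"].values
        n_lowq = int(lowq.sum())
        lowest = np.argsort(qc["total_umi"].values, kind="stable")[:n_lowq]
        assert set(lowest) == set(np.where(lowq)[0])


def _boundary_adata():
    # 600 genes so the gene-count threshold can be cleared; three probe
    # cells with totals 1000 / 1001 / 2000 spread over 501 genes
    n_genes = 600
    rows = []
    for total in (1000, 1001, 2000):
        counts = np.zeros(n_genes, int)
        counts[:500] = 1
        counts[500] = total - 500
        rows.append(counts)
    # filler cells keeping every gene detected in >= 10 cells
    filler = np.ones((20, n_genes), int) * 3
    filler[:, 0] += 2000
    counts = np.vstack(rows + [filler])
    return make_adata(counts)


class TestCellGeneFilters:
    def test_umi_boundary_strictly_greater(self):
        adata = _boundary_adata()
        thr = QCThresholds(min_umi=1000, min_genes=400, max_mito_frac=1.0,
                           min_cells_per_gene=1, max_umi={"all": 10**9},
                           max_genes={"all": 10**9})
        out = preprocess.filter_cells_genes(adata, thr)
        assert "c0" not in out.obs_names          # UMI exactly 1000: removed
        assert "c1" in out.obs_names              # UMI 1001: kept

    def test_gene_detected_in_9_vs_10_cells(self):
        counts = np.ones((30, 700), int) * 2
        counts[:, 0] = 0
        counts[:9, 0] = 1     # detected in 9 cells -> dropped
        counts[:10, 1] = 5    # detected in all 30 -> kept
        adata = make_adata(counts)
        thr = QCThresholds(min_umi=100, min_genes=100, max_mito_frac=1.0,
                           min_cells_per_gene=10, max_umi={"all": 10**9},
                           max_genes={"all": 10**9})
        out = preprocess.filter_cells_genes(adata, thr)
        assert "g0" not in out.var_names
        assert "g1" in out.var_names

    def test_all_cells_fail_raises(self):
        adata = make_adata(np.ones((5, 10), int))
        with pytest.raises(EmptyOutputError):
            preprocess.filter_cells_genes(adata, QCThresholds())

    def test_idempotent_with_resolved_thresholds(self, small_cohort):
        adata, _ = small_cohort
        thr = QCThresholds()
        once = preprocess.filter_cells_genes(adata, thr)
        report = once.uns["qc_report"].set_index("donor")
        resolved = QCThresholds(
            max_umi=report["max_umi"].to_dict(),
            max_genes=report["max_genes"].to_dict())
        twice = preprocess.filter_cells_genes(once, resolved)
        assert twice.shape == once.shape
        assert list(twice.obs_names) == list(once.obs_names)

    def test_qc_removes_planted_lowq(self, small_cohort):
        adata, truth = small_cohort
        out = preprocess.filter_cells_genes(adata)
        kept = truth.cells.loc[out.obs_names]
        assert not kept["lowq"].any()


class TestNormalize:
    def test_forced_arithmetic(self):
        counts = np.zeros((1, 200), int)
        counts[0, :100] = 198          # filler
        counts[0, 100] = 2
        counts[0, 0] = 20000 - 198 * 100 - 2 + 198
        adata = make_adata(counts)
        total = counts.sum()
        norm = preprocess.normalize_log(adata, scale_factor=10000.0)
        x = norm.X[0, 100]
        expected = np.log2(1 + 2 / total * 10000)
        assert np.isclose(x, expected)

    def test_count2_in_total_20000_gives_log_value_1(self):
        counts = np.zeros((1, 3), int)
        counts[0] = [2, 19990, 8]
        adata = make_adata(counts)
        norm = preprocess.normalize_log(adata, scale_factor=10000.0)
        assert np.isclose(norm.X[0, 0], 1.0)   # scaled 1.0 -> log2(2) = 1
        assert norm.X[0, 0] == pytest.approx(1.0)

    def test_zero_stays_zero_and_cell_sums(self, small_cohort):
        adata, _ = small_cohort
        filtered = preprocess.filter_cells_genes(adata)
        norm = preprocess.normalize_log(filtered)
        X = sp.csr_matrix(norm.X)
        assert (X.data > 0).all()
        # inverse transform: per-cell pre-log sums equal the scale factor
        prelog = X.copy()
        prelog.data = 2.0 ** prelog.data - 1.0
        sums = np.asarray(prelog.sum(axis=1)).ravel()
        assert np.allclose(sums, 10000.0)

    def test_scale_equivariance(self):
        counts = np.array([[1, 2, 3, 4]], dtype=int)
        a1 = make_adata(counts)
        a2 = make_adata(counts * 7)
        n1 = preprocess.normalize_log(a1)
        n2 = preprocess.normalize_log(a2)
        assert np.allclose(np.asarray(n1.X.todense()), np.asarray(n2.X.todense()))

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            preprocess.normalize_log(make_adata([[0, 0]]))


class TestHVGSelection:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, (100, 50))
        counts[:, 0] = 7   # zero-variance gene
        adata = make_adata(counts)
        norm = preprocess.normalize_log(adata)
        fit = preprocess.select_hvgs(norm, mean_min=0.01, disp_min=0.0)
        # after library scaling a constant-count gene retains tiny variance
        # from library-size division; its CV^2 stays far below the trend
        assert not fit.table.loc["g0", "selected"]

    def test_planted_high_dispersion_genes_recovered(self):
        rng = np.random.default_rng(1)
        n_cells, n_genes = 400, 1000
        mean = rng.uniform(1.0, 20.0, n_genes)
        r_low, r_high = 1 / 0.05, 1 / 3.0
        counts = rng.negative_binomial(r_low, r_low / (r_low + mean),
                                       (n_cells, n_genes))
        hi = rng.choice(n_genes, 50, replace=False)
        counts[:, hi] = rng.negative_binomial(
            r_high, r_high / (r_high + mean[hi]), (n_cells, 50))
        adata = make_adata(counts)
        norm = preprocess.normalize_log(adata)
        fit = preprocess.select_hvgs(norm, mean_min=0.05, disp_min=0.05)
        assert set(f"g{i}" for i in hi) <= set(fit.selected)

    def test_fit_matches_independent_glm_oracle(self):
        """IRLS gamma-GLM fit agrees with statsmodels (independent
        implementation) to 1e-6 relative on a 200-gene fixture."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        mu = rng.uniform(0.1, 20.0, 200)
        cv2 = (3.0 / mu + 0.4) * rng.gamma(20.0, 1 / 20.0, 200)
        a1, alpha0, _ = _fit_gamma_cv2(mu, cv2)
        X = np.column_stack([np.ones_like(mu), 1.0 / mu])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.GLM(cv2, X, family=sm.families.Gamma(
                sm.families.links.Identity())).fit()
        assert a1 == pytest.approx(ref.params[1], rel=1e-6)
        assert alpha0 == pytest.approx(ref.params[0], rel=1e-6)

    def test_order_invariance(self, norm_cohort):
        norm, _, _ = norm_cohort
        fit = preprocess.select_hvgs(norm)
        rng = np.random.default_rng(3)
        gp = rng.permutation(norm.n_vars)
        cp = rng.permutation(norm.n_obs)
        shuffled = norm[cp, :][:, gp].copy()
        fit2 = preprocess.select_hvgs(shuffled)
        assert set(fit.selected) == set(fit2.selected)

    def test_insufficient_genes_error(self):
        adata = make_adata(np.ones((5, 12), int))
        norm = preprocess.normalize_log(adata)
        with pytest.raises(InsufficientDataError):
            preprocess.select_hvgs(norm, mean_min=1e9)


class TestFlaggedGeneRemoval:
    def test_817_minus_12_gives_805(self):
        genes = [f"G{i}" for i in range(805)] + [
            "MT-1", "MT-2", "MT-3", "MT-4", "RPS1", "RPS2", "RPL1", "RPL2",
            "HSPA1", "HSPA2", "HSPB1", "HSP90"]
        assert len(genes) == 817
        kept = preprocess.remove_flagged_genes(genes)
        assert len(kept) == 805

    def test_empty_flag_list_is_identity(self):
        genes = ["MT-1", "A", "B"]
        assert preprocess.remove_flagged_genes(genes, patterns=()) == genes

    def test_all_flagged_warns_and_empties(self):
        with pytest.warns(UserWarning):
            out = preprocess.remove_flagged_genes(["MT-1", "MT-2"])
        assert out == []

    def test_explicit_flag_set(self):
        assert preprocess.remove_flagged_genes(["a", "b", "c"], flagged={"b"}) == ["a", "c"]


class TestBatchAdjustment:
    def _fixture(self, seed=0, n_genes=50, shift=1.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(1.0, 1.0, (n_genes, 200))
        batch = np.array(["a"] * 80 + ["b"] * 70 + ["c"] * 50)
        X[:20, batch == "b"] += shift
        return X, batch

    def test_single_batch_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 20))
        with pytest.warns(UserWarning):
            out = preprocess.regress_batch(X, np.repeat("a", 20))
        assert np.array_equal(out, X)

    def test_singleton_batch_error_names_batch(self):
        X = np.random.default_rng(0).normal(size=(10, 21))
        batch = np.array(["a"] * 20 + ["solo"])
        with pytest.raises(ValueError, match="solo"):
            preprocess.regress_batch(X, batch)

    def test_planted_shift_removed(self):
        """Additive per-gene shifts centered on 1.0 in one batch of a
        20-gene matrix are removed to < 0.05 residual between-batch mean
        difference (per-gene heterogeneity is the regime the
        empirical-Bayes location prior is built for)."""
        rng = np.random.default_rng(4)
        X = rng.normal(1.0, 1.0, (20, 2000))
        batch = np.array(["a"] * 800 + ["b"] * 700 + ["c"] * 500)
        X[:, batch == "b"] += rng.normal(1.0, 0.3, (20, 1))
        out = preprocess.regress_batch(X, batch)
        diff = out[:, batch == "b"].mean(axis=1) - out[:, batch == "a"].mean(axis=1)
        assert np.abs(diff).max() < 0.05

    def test_agreement_with_reference_implementation(self):
        """Dual route: the in-package adjustment vs scanpy's ComBat on a
        50 x 200 fixture, max abs diff < 1e-6."""
        import anndata as ad
        import scanpy as sc

        X, batch = self._fixture()
        mine = preprocess.regress_batch(X, batch)
        A = ad.AnnData(X=X.T.copy())
        A.obs["batch"] = batch
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(A, key="batch")
        assert np.abs(mine - A.X.T).max() < 1e-6

    def test_batch_variance_mostly_removed_and_mean_roughly_kept(self):
        """Under the generator's batch model (independent per-donor
        per-gene log-scale factors), >= 95% of between-batch variance is
        removed; the pooled per-gene mean moves by far less than the
        planted effect scale."""
        rng = np.random.default_rng(5)
        n_genes, per_batch = 100, 150
        base = rng.normal(2.0, 1.0, (n_genes, 1))
        blocks, batch = [], []
        for b in "abc":
            factors = rng.normal(0.0, 0.3, (n_genes, 1))   # planted batch effect
            blocks.append(base + factors + rng.normal(0, 0.5, (n_genes, per_batch)))
            batch += [b] * per_batch
        X, batch = np.hstack(blocks), np.array(batch)
        out = preprocess.regress_batch(X, batch)

        def between_var(M):
            means = np.stack([M[:, batch == b].mean(axis=1) for b in "abc"])
            return means.var(axis=0).mean()

        assert between_var(out) < 0.05 * between_var(X)
        assert np.abs(out.mean(axis=1) - X.mean(axis=1)).max() < 0.1

    def test_output_dimensions_and_zero_variance_genes(self):
        X, batch = self._fixture()
        X[5] = 2.5  # constant gene
        out = preprocess.regress_batch(X, batch)
        assert out.shape == X.shape
        assert np.array_equal(out[5], X[5])
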