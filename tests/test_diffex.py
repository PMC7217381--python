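"""Combined frequency + level differential expression statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mkbias import diffex, preprocess, simulate

from conftest import make_adata


def _exact_ranksum_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    stats_all = []
    for comb in itertools.combinations(range(len(pooled)), n):
        stats_all.append(ranks[list(comb)].sum())
    stats_all = np.array(stats_all)
    mu = stats_all.mean()
    return np.mean(np.abs(stats_all - mu) >= abs(obs - mu) - 1e-12)


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all 20 arrangements of ranks; the observed split is one of the
        # two most extreme -> p = 2/20
        assert diffex.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert diffex.wilcoxon_rank_sum([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=4)
            assert diffex.wilcoxon_rank_sum(a, b) == pytest.approx(
                _exact_ranksum_p(a, b))

    def test_approximation_close_to_exact(self):
        """Normal approximation with continuity correction vs exact
        enumeration on 200 random n=8 cases: max abs difference < 0.02."""
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(200):
            a, b = rng.normal(size=8), rng.normal(size=8)
            p_exact = diffex.wilcoxon_rank_sum(a, b)   # n<=8, no ties -> exact
            p_approx = float(stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=True).pvalue)
            worst = max(worst, abs(p_exact - p_approx))
        assert worst < 0.02

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            diffex.wilcoxon_rank_sum([], [1.0])


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert diffex.fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_hand_enumerated_hypergeometric(self):
        # sum of hypergeometric point masses <= P(observed) over all
        # tables with the same margins
        table = [[3, 1], [1, 3]]
        p_obs = stats.hypergeom.pmf(3, 8, 4, 4)
        p_two = sum(stats.hypergeom.pmf(k, 8, 4, 4)
                    for k in range(5)
                    if stats.hypergeom.pmf(k, 8, 4, 4) <= p_obs + 1e-12)
        assert diffex.fisher_exact_2x2(table) == pytest.approx(p_two)
        assert diffex.fisher_exact_2x2(table) == pytest.approx(0.485714, abs=1e-6)

    def test_reconstructed_marker_frequency_comparison(self):
        """Expressing frequencies 534/1668 (mutant) vs 100/678 (healthy
        wild type) differ at p < 0.001."""
        p = diffex.fisher_exact_2x2([[534, 1668 - 534], [100, 678 - 100]])
        assert p < 0.001

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            diffex.fisher_exact_2x2([[1, -1], [0, 2]])


class TestFisherCombine:
    def test_all_ones(self):
        assert diffex.fisher_combine([1.0, 1.0]) == 1.0

    def test_two_nominal_p05(self):
        # X^2 = -4 ln 0.05 = 11.98 on 4 df
        assert diffex.fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=2e-4)

    def test_single_p_identity(self):
        for p in (0.3, 0.01, 1.0):
            assert diffex.fisher_combine([p]) == pytest.approx(p)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = diffex.fisher_combine([0.0, 0.5])
        assert 0 < p < 1e-100


class TestBHAdjust:
    def test_hand_stepup(self):
        assert np.allclose(diffex.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(diffex.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_p(self, ps):
        q = diffex.bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(100)
        assert np.allclose(diffex.bh_adjust(p),
                           multipletests(p, method="fdr_bh")[1])


def _marker_fixture(seed=0, n_null=200, n_markers=10, n_weak=10):
    """Two clusters; markers with strong planted effects (log2FC ~1,
    frac 0.6 vs 0.05), weak genes with log2FC 0.3 and no frequency
    effect, and identical null genes."""
    rng = np.random.default_rng(seed)
    n1, n2 = 150, 300
    n_genes = n_null + n_markers + n_weak
    X = np.zeros((n1 + n2, n_genes))
    counts = np.zeros_like(X, dtype=int)
    labels = np.array([0] * n1 + [1] * n2)
    base_detect = rng.random((n1 + n2, n_genes)) < 0.5
    X[base_detect] = rng.normal(2.0, 0.5, base_detect.sum())
    for g in range(n_markers):                       # markers in cluster 0
        det0 = rng.random(n1) < 0.6
        det1 = rng.random(n2) < 0.05
        X[:n1, g] = np.where(det0, rng.normal(2.5, 0.4, n1), 0.0)
        X[n1:, g] = np.where(det1, rng.normal(2.5, 0.4, n2), 0.0)
    for g in range(n_markers, n_markers + n_weak):   # weak level shift only
        X[:n1, g] = np.abs(rng.normal(1.0, 0.3, n1)) + 0.3
        X[n1:, g] = np.abs(rng.normal(1.0, 0.3, n2))
    counts = (X > 0).astype(int) * np.maximum(1, np.round(2**X - 1)).astype(int)
    adata = make_adata(counts)
    adata.X = X
    import scipy.sparse as sp
    adata.layers["counts"] = sp.csr_matrix(counts)
    return adata, labels, n_markers, n_weak


class TestClusterMarkers:
    def test_planted_markers_recovered_weak_excluded(self):
        adata, labels, n_markers, n_weak = _marker_fixture()
        table = diffex.cluster_markers(adata, labels)
        cl0 = table[(table["group"] == 0) & table["passes_marker_filter"]]
        found = set(cl0["gene"])
        assert {f"g{i}" for i in range(n_markers)} <= found
        weak = {f"g{i}" for i in range(n_markers, n_markers + n_weak)}
        assert not (weak & found)

    def test_identical_clusters_no_markers(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, (100, 50))
        adata = make_adata(counts)
        norm = preprocess.normalize_log(adata)
        labels = np.array([0] * 50 + [1] * 50)
        table = diffex.cluster_markers(norm, labels)
        assert table["passes_marker_filter"].sum() == 0

    def test_top50_cap(self):
        """With ~80 genes passing the filters in one cluster, exactly 50
        are reported."""
        rng = np.random.default_rng(4)
        n1 = n2 = 100
        n_strong = 80
        X = np.zeros((n1 + n2, n_strong + 40))
        X[:, n_strong:] = rng.normal(1.0, 0.2, (n1 + n2, 40))
        for g in range(n_strong):
            X[:n1, g] = np.where(rng.random(n1) < 0.8,
                                 rng.normal(3.0, 0.3, n1), 0.0)
            X[n1:, g] = np.where(rng.random(n2) < 0.1,
                                 rng.normal(3.0, 0.3, n2), 0.0)
        counts = np.maximum(0, np.round(2**X - 1)).astype(int)
        adata = make_adata(counts)
        adata.X = X
        import scipy.sparse as sp
        adata.layers["counts"] = sp.csr_matrix(counts)
        labels = np.array([0] * n1 + [1] * n2)
        table = diffex.cluster_markers(adata, labels)
        cl0 = table[table["group"] == 0]
        assert cl0["passes_marker_filter"].sum() >= 60
        assert cl0["reported_marker"].sum() == 50

    def test_cell_order_permutation_invariant(self):
        adata, labels, *_ = _marker_fixture(seed=5, n_null=50)
        t1 = diffex.cluster_markers(adata, labels)
        rng = np.random.default_rng(6)
        perm = rng.permutation(adata.n_obs)
        t2 = diffex.cluster_markers(adata[perm].copy(), labels[perm])
        for cl in (0, 1):
            a = t1[t1["group"] == cl].set_index("gene")
            b = t2[t2["group"] == cl].set_index("gene")
            assert np.allclose(a["p_combined"], b.loc[a.index, "p_combined"])

    def test_log2fc_sign_matches_mean_difference(self):
        adata, labels, *_ = _marker_fixture(seed=7, n_null=50)
        table = diffex.cluster_markers(adata, labels)
        X = np.asarray(adata.X)
        for _, row in table[table["passes_marker_filter"]].iterrows():
            g = adata.var_names.get_loc(row["gene"])
            mask = labels == row["group"]
            diff = X[mask, g].mean() - X[~mask, g].mean()
            assert np.sign(diff) == np.sign(row["log2FC"])

    def test_single_cluster_error_and_tiny_cluster_warning(self):
        adata, labels, *_ = _marker_fixture(seed=8, n_null=30)
        with pytest.raises(ValueError):
            diffex.cluster_markers(adata, np.zeros(adata.n_obs, int))
        labels2 = labels.copy()
        labels2[:2] = 2
        with pytest.warns(UserWarning, match="fewer than 3"):
            diffex.cluster_markers(adata, labels2)


class TestGenotypeTest:
    def test_identical_groups_combined_p_near_one(self):
        rng = np.random.default_rng(9)
        counts = np.tile(rng.poisson(3.0, (1, 30)), (60, 1))
        adata = make_adata(counts)
        norm = preprocess.normalize_log(adata)
        genotype = np.array(["a"] * 30 + ["b"] * 30)
        res = diffex.genotype_expression_test(norm, genotype, "g0")
        assert res["p_combined"].iloc[0] > 0.9

    def test_planted_frequency_effect_detected(self):
        """Planted frequencies 0.32 vs 0.147 at the printed group sizes
        give combined p < 0.001 in nearly every replicate."""
        hits = 0
        reps = 20
        for seed in range(reps):
            adata, truth = simulate.generate_genotyped_cells(
                simulate.CohortParams(seed=seed, n_genes=60, program_size=5))
            norm = preprocess.normalize_log(adata)
            sub = norm[(norm.obs["genotype"] != "WT-patient").values].copy()
            res = diffex.genotype_expression_test(
                sub, sub.obs["genotype"].values, sub.var_names[0])
            hits += res["p_combined"].iloc[0] < 0.001
        assert hits >= reps - 1

    def test_gene_absent_error(self):
        adata = make_adata(np.ones((10, 5), int))
        with pytest.raises(ValueError):
            diffex.genotype_expression_test(adata, ["a"] * 5 + ["b"] * 5, "nope")


def test_welch_t_from_summary_matches_scipy():
    rng = np.random.default_rng(10)
    a, b = rng.normal(0, 1, 11), rng.normal(1, 2, 8)
    t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
    t, p = diffex.welch_t_from_summary(
        a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
        b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b))
    assert t == pytest.approx(t_ref)
    assert p == pytest.approx(p_ref)
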