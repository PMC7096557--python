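"""Network construction and module detection: hand-worked TOM values,
independent numerical oracles (two-pass correlation, SVD, correlation
kME), planted-partition recovery and the declared conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import ctnet
from ctnet.coexpression import kme_table, _relabel_by_size
from helpers import block_expression, gene_index


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def two_pass_correlation(X):
    """Brute-force two-pass covariance/correlation oracle."""
    n_genes, n_obs = X.shape
    means = [sum(row) / n_obs for row in X]
    cov = np.empty((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(n_genes):
            cov[i, j] = sum(
                (X[i, k] - means[i]) * (X[j, k] - means[j]) for k in range(n_obs)
            ) / (n_obs - 1)
    out = np.empty_like(cov)
    for i in range(n_genes):
        for j in range(n_genes):
            out[i, j] = cov[i, j] / np.sqrt(cov[i, i] * cov[j, j])
    return out


class TestCorrelation:
    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 40))
        assert np.abs(
            ctnet.correlation_matrix(X) - two_pass_correlation(X)
        ).max() < 1e-10

    def test_duplicate_and_anticorrelated_rows(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        X = np.vstack([x, x, -x, rng.standard_normal(30)])
        cor = ctnet.correlation_matrix(X)
        assert cor[0, 1] == pytest.approx(1.0)
        assert cor[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(cor) == 1.0)

    def test_too_few_nuclei_names_cell_type(self):
        with pytest.raises(ValueError, match="Ast"):
            ctnet.correlation_matrix(np.ones((5, 2)), cell_type="Ast")


class TestAdjacencyAndTom:
    def test_adjacency_values(self):
        cor = np.array([[1.0, -0.8], [-0.8, 1.0]])
        A = ctnet.adjacency(cor, 6)
        assert A[0, 1] == pytest.approx(0.262144)
        assert np.all(np.diag(A) == 1.0)
        assert ctnet.adjacency(np.array([[1.0, 0.0], [0.0, 1.0]]), 3)[0, 1] == 0.0
        with pytest.raises(ValueError, match=">= 1"):
            ctnet.adjacency(cor, 0.5)

    def test_three_gene_hand_case(self):
        # all pairwise cor +0.5, beta 1: l = 0.25, k = 1, TOM = 0.75/1.5 = 0.5
        cor = np.full((3, 3), 0.5)
        np.fill_diagonal(cor, 1.0)
        tom = ctnet.signed_tom(ctnet.adjacency(cor, 1), cor)
        off = tom[np.triu_indices(3, 1)]
        assert np.allclose(off, 0.5)

    def test_perfect_and_null_limits(self):
        cor = np.ones((4, 4))
        tom = ctnet.signed_tom(ctnet.adjacency(cor, 3), cor)
        assert np.allclose(tom, 1.0)
        # a gene uncorrelated with everything has a zero TOM row
        cor = np.full((4, 4), 0.6)
        np.fill_diagonal(cor, 1.0)
        cor[3, :3] = cor[:3, 3] = 0.0
        tom = ctnet.signed_tom(ctnet.adjacency(cor, 2), cor)
        assert np.allclose(tom[3, :3], 0.0)

    def test_reduces_to_unsigned_for_nonnegative_correlations(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 60))
        cor = np.abs(ctnet.correlation_matrix(X))
        A = ctnet.adjacency(cor, 4)
        signed = ctnet.signed_tom(A, cor)
        # unsigned oracle
        A0 = A.copy()
        np.fill_diagonal(A0, 0.0)
        L = A0 @ A0
        k = A0.sum(axis=1)
        unsigned = (L + A0) / (np.minimum.outer(k, k) + 1 - A0)
        np.fill_diagonal(unsigned, 1.0)
        assert np.abs(signed - unsigned).max() < 1e-12

    @given(
        seed=st.integers(0, 2**16),
        n_genes=st.integers(3, 40),
        n_obs=st.integers(3, 50),
        beta=st.integers(1, 12),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_tom_bounds_and_symmetry(self, seed, n_genes, n_obs, beta):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_genes, n_obs))
        cor = ctnet.correlation_matrix(X)
        tom = ctnet.signed_tom(ctnet.adjacency(cor, beta), cor)
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1.0)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ctnet.signed_tom(np.abs(bad), bad)


class TestSoftThreshold:
    def test_mean_connectivity_nonincreasing_in_beta(self):
        rng = np.random.default_rng(3)
        cor = ctnet.correlation_matrix(rng.standard_normal((40, 30)))
        abs_cor = np.abs(cor)
        np.fill_diagonal(abs_cor, 0)
        means = [(abs_cor**b).sum(axis=1).mean() for b in range(1, 21)]
        assert np.all(np.diff(means) <= 1e-12)

    def test_degenerate_all_equal_correlations_fall_back(self):
        cor = np.ones((10, 10))
        with pytest.warns(UserWarning, match="falling back"):
            assert ctnet.pick_soft_threshold(cor) == 6

    def test_reproducible_choice_on_structured_data(self):
        X, _ = block_expression([40, 40], 0.6, 120, 150, np.random.default_rng(4))
        cor = ctnet.correlation_matrix(X)
        b1 = ctnet.pick_soft_threshold(cor)
        b2 = ctnet.pick_soft_threshold(cor)
        assert b1 == b2 and 1 <= b1 <= 20


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _tom_of(X, beta=6):
    cor = ctnet.correlation_matrix(X)
    return ctnet.signed_tom(ctnet.adjacency(cor, beta), cor)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        for seed in range(3):
            X, truth = block_expression([40, 40], 0.9, 0, 200, np.random.default_rng(seed))
            labels = ctnet.detect_modules(_tom_of(X))
            assert adjusted_rand_score(truth, labels) >= 0.9
            assert len(set(labels) - {0}) == 2

    def test_small_block_left_unassigned(self):
        X, truth = block_expression([10], 0.9, 190, 200, np.random.default_rng(0))
        labels = ctnet.detect_modules(_tom_of(X), min_module_size=30)
        assert np.all(labels[truth == 1] == 0)

    def test_pure_noise_mostly_unassigned(self):
        frac = []
        for seed in range(10):
            X, _ = block_expression([], 0.5, 300, 150, np.random.default_rng(seed))
            labels = ctnet.detect_modules(_tom_of(X))
            frac.append((labels == 0).mean())
        assert np.mean(frac) >= 0.8

    def test_fewer_genes_than_min_size_warns(self):
        X, _ = block_expression([10], 0.9, 0, 50, np.random.default_rng(1))
        with pytest.warns(UserWarning, match="no modules"):
            labels = ctnet.detect_modules(_tom_of(X), min_module_size=30)
        assert np.all(labels == 0)


class TestEigengene:
    def test_identical_genes_module(self):
        rng = np.random.default_rng(5)
        profile = rng.standard_normal(40)
        X = np.tile(profile, (5, 1))
        eg, varexpl = ctnet.module_eigengene(X, np.ones(5, dtype=int))
        assert varexpl[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eg["ME1"], z)[0, 1]) == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 50))
        eg, _ = ctnet.module_eigengene(X, np.ones(30, dtype=int))
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(Xs)
        v = vt[0]
        diff = min(np.abs(eg["ME1"].to_numpy() - v).max(), np.abs(eg["ME1"].to_numpy() + v).max())
        assert diff < 1e-8

    def test_orientation_convention(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X, labels = block_expression([10, 12], 0.7, 5, 60, rng)
            labels = np.where(labels == 0, 0, labels)
            eg, _ = ctnet.module_eigengene(X, labels)
            for lab in (1, 2):
                rows = X[labels == lab]
                Xs = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
                assert np.corrcoef(eg[f"ME{lab}"], Xs.mean(axis=0))[0, 1] >= 0


class TestMergeAndPrune:
    def test_modules_sharing_a_latent_merge(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(100)
        X = np.vstack([
            3 * z[None, :] + rng.standard_normal((20, 100)),
            3 * z[None, :] + rng.standard_normal((20, 100)),
        ])
        labels = np.repeat([1, 2], 20)
        merged = ctnet.merge_modules(X, labels, merge_cut_height=0.2)
        assert len(set(merged) - {0}) == 1

    def test_independent_modules_stay_separate(self):
        rng = np.random.default_rng(9)
        X, labels = block_expression([20, 20], 0.9, 0, 100, rng)
        merged = ctnet.merge_modules(X, labels, merge_cut_height=0.2)
        assert len(set(merged) - {0}) == 2

    def test_single_module_unchanged(self):
        rng = np.random.default_rng(10)
        X, labels = block_expression([20], 0.8, 10, 50, rng)
        assert np.array_equal(ctnet.merge_modules(X, labels), _relabel_by_size(labels))

    def test_kme_matches_correlation_oracle_and_prunes_noise(self):
        rng = np.random.default_rng(11)
        X, labels = block_expression([25], 0.8, 1, 400, rng)
        labels = labels.copy()
        labels[-1] = 1  # force a noise gene into the module
        ms = ctnet.kme_prune(X, gene_index(26), labels, min_kme=0.2)
        assert ms.labels[-1] == 0  # noise gene pruned
        assert (ms.labels[:25] == 1).all()
        eg, _ = ctnet.module_eigengene(X, ms.labels)
        oracle = np.array([np.corrcoef(X[i], eg["ME1"])[0, 1] for i in range(26)])
        assert np.abs(ms.kme["ME1"].to_numpy() - oracle).max() < 1e-10

    def test_gene_equal_to_eigengene_retained(self):
        rng = np.random.default_rng(12)
        X, labels = block_expression([20], 0.9, 0, 80, rng)
        ms = ctnet.kme_prune(X, gene_index(20), labels, min_kme=0.2)
        assert np.all(ms.labels == 1)
        assert ms.kme["ME1"].abs().min() > 0.8


class TestHubExport:
    def _module_set(self, n_genes=123, n_obs=80, seed=13):
        rng = np.random.default_rng(seed)
        X, labels = block_expression([n_genes], 0.6, 0, n_obs, rng)
        return ctnet.kme_prune(X, gene_index(n_genes), labels, min_kme=0.0), X

    def test_top_50_of_a_123_gene_module(self):
        ms, X = self._module_set()
        tom = _tom_of(X, beta=2)
        nodes, edges = ctnet.export_top_hub_network(ms, tom, 1, n=50, edge_floor=0.0)
        assert len(nodes) == 50
        assert len(edges) == 50 * 49 // 2  # edge_floor 0: complete graph
        kmes = nodes["kme"].to_numpy()
        assert np.all(np.diff(kmes) <= 1e-12)
        # ties (if any) and ordering: re-sorting by (-kme, gene) is a no-op
        resorted = nodes.sort_values(["kme", "gene"], ascending=[False, True], ignore_index=True)
        assert list(resorted["gene"]) == list(nodes["gene"])

    def test_small_module_exports_everything(self):
        ms, X = self._module_set(n_genes=20)
        tom = _tom_of(X, beta=2)
        nodes, _ = ctnet.export_top_hub_network(ms, tom, 1, n=50)
        assert len(nodes) == 20

    def test_disease_flag_annotated(self):
        ms, X = self._module_set(n_genes=30)
        tom = _tom_of(X, beta=2)
        nodes, _ = ctnet.export_top_hub_network(
            ms, tom, 1, n=10, disease_genes={nodes_gene for nodes_gene in ms.genes[:5]}
        )
        flagged = set(nodes.loc[nodes["is_disease_gene"], "gene"])
        assert flagged == set(ms.genes[:5]) & set(nodes["gene"])


def test_module_set_pipeline_is_deterministic(default_run):
    """The full coexpression stage is seed-free: rerunning it on the same
    expression matrix reproduces labels bit for bit."""
    net = default_run["networks"]["Ast"]
    X = default_run["class_X"]["Ast"]
    a = ctnet.detect_module_set(net, X)
    b = ctnet.detect_module_set(net, X)
    assert np.array_equal(a.labels, b.labels)
    assert np.allclose(a.eigengenes.to_numpy(), b.eigengenes.to_numpy())
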