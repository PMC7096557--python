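"""QC, size-factor normalisation, CPM, EB batch correction and HVG
selection, checked against closed-form cases, simulations with known
structure and an independent batch-correction implementation."""

import numpy as np
import pandas as pd
import pytest

import ctnet
from ctnet.dataset import ExpressionDataset
from helpers import gene_index


def _dataset(counts, obs=None, **kw):
    counts = np.asarray(counts)
    n_genes, n_nuclei = counts.shape
    if obs is None:
        obs = pd.DataFrame(
            {"cell_class": ["A"] * n_nuclei},
            index=pd.Index([f"n{i}" for i in range(n_nuclei)]),
        )
    return ExpressionDataset(counts=counts, genes=gene_index(n_genes), obs=obs, **kw)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def test_zero_count_nucleus_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(50, 30))
        counts[:, 7] = 0
        out = ctnet.qc_filter(_dataset(counts))
        assert out.n_nuclei == 29
        assert "n7" not in out.nuclei

    def test_excluded_genes_removed_exactly(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(50, 30))
        excl = [f"g{i:04d}" for i in (0, 3, 10, 20, 44)]
        out = ctnet.qc_filter(_dataset(counts), exclude_genes=excl)
        assert out.n_genes == 45
        assert not set(excl) & set(out.genes)

    def test_homogeneous_dataset_passes_nearly_untouched(self):
        """On homogeneous libraries the 3-MAD lower-tail rule removes at
        most ~1% of nuclei."""
        removed = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(8, size=(200, 400))
            out = ctnet.qc_filter(_dataset(counts))
            removed.append(1 - out.n_nuclei / 400)
        assert np.mean(removed) <= 0.01

    def test_all_removed_raises(self):
        counts = np.zeros((20, 5), dtype=int)
        with pytest.raises(ValueError, match="n_mads|every nucleus"):
            ctnet.qc_filter(_dataset(counts))


# ---------------------------------------------------------------------------
# size factors / CPM
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_equal_libraries_give_unit_factors(self):
        counts = np.tile([[2], [3], [5]], (1, 4))
        ds = ctnet.size_factor_normalize(_dataset(counts))
        assert np.allclose(ctnet.preprocess.size_factors(_dataset(counts)), 1.0)
        assert np.allclose(ds.lognorm, np.log2(counts + 1.0))

    def test_scaling_one_nucleus_scales_its_factor(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(10, size=(100, 500))
        sf0 = ctnet.preprocess.size_factors(_dataset(counts))
        doubled = counts.copy()
        doubled[:, 0] *= 2
        sf1 = ctnet.preprocess.size_factors(_dataset(doubled))
        # ratio approaches exactly 2 as the renormalising mean stabilises
        assert sf1[0] / sf0[0] == pytest.approx(2.0, rel=5e-3)
        a = ctnet.size_factor_normalize(_dataset(counts)).lognorm[:, 0]
        b = ctnet.size_factor_normalize(_dataset(doubled)).lognorm[:, 0]
        assert np.allclose(a, b, atol=0.02)

    def test_size_factor_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3, size=(50, 77)) + 1
        assert ctnet.preprocess.size_factors(_dataset(counts)).mean() == pytest.approx(1.0)

    def test_cpm_definition_and_column_sums(self):
        counts = np.array([[2, 4], [3, 0], [5, 6]])
        out = ctnet.cpm(_dataset(counts))
        assert np.allclose(out[:, 0], [200000, 300000, 500000])
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_all_zero_gene_stays_zero(self):
        counts = np.array([[0, 0, 0], [5, 6, 7]])
        assert np.all(ctnet.cpm(_dataset(counts))[0] == 0)


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def _batched(seed=0, shift=1.0, n_per_batch=200, n_genes=150):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_batch
    counts = rng.poisson(8, size=(n_genes, n))  # placeholder; lognorm is what matters
    obs = pd.DataFrame(
        {
            "cell_class": ["A"] * n,
            "batch": ["B0"] * n_per_batch + ["B1"] * n_per_batch,
        },
        index=pd.Index([f"n{i}" for i in range(n)]),
    )
    ds = _dataset(counts, obs=obs)
    base = rng.normal(3, 1, size=n_genes)
    delta = rng.normal(0, shift, size=n_genes)
    X = base[:, None] + rng.normal(0, 0.8, size=(n_genes, n))
    X[:, n_per_batch:] += delta[:, None]
    ds.lognorm = X
    return ds, delta


class TestCorrectBatch:
    def test_single_batch_is_identity(self):
        ds, _ = _batched()
        ds.obs["batch"] = "B0"
        out = ctnet.correct_batch(ds)
        assert np.allclose(out.lognorm, ds.lognorm, atol=1e-8)

    def test_constant_shift_removed(self):
        ds, _ = _batched(seed=4)
        out = ctnet.correct_batch(ds)
        b0 = out.lognorm[:, :200].mean(axis=1)
        b1 = out.lognorm[:, 200:].mean(axis=1)
        assert np.abs(b0 - b1).max() < 0.05

    def test_idempotent_within_tolerance(self):
        ds, _ = _batched(seed=5)
        once = ctnet.correct_batch(ds)
        twice = ctnet.correct_batch(once)
        assert np.abs(once.lognorm - twice.lognorm).max() < 0.05

    def test_matches_scanpy_combat(self):
        """Independent cross-check against scanpy's ComBat on the same
        shifted simulation."""
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        ds, _ = _batched(seed=6)
        ours = ctnet.correct_batch(ds).lognorm
        ad = anndata.AnnData(
            X=ds.lognorm.T.copy(), obs=pd.DataFrame({"batch": ds.obs["batch"].to_numpy()}),
        )
        scanpy.pp.combat(ad, key="batch")
        theirs = ad.X.T
        assert np.abs(ours - theirs).mean() < 0.02
        assert np.abs(ours - theirs).max() < 0.2

    def test_tiny_batch_raises(self):
        ds, _ = _batched()
        ds.obs.loc[ds.obs.index[1:], "batch"] = "B1"
        with pytest.raises(ValueError, match="fewer than 2"):
            ctnet.correct_batch(ds)

    def test_planted_batch_variance_mostly_removed(self, default_run):
        """Median per-gene batch R-squared drops by >= 90% on the default
        synthetic scenario."""
        ds = ctnet.size_factor_normalize(ctnet.qc_filter(default_run["raw"]))
        corrected = ctnet.correct_batch(ds)
        batch = (ds.obs["batch"] == "B1").to_numpy().astype(float)
        batch = (batch - batch.mean()) / batch.std()

        def med_r2(X):
            Xc = X - X.mean(axis=1, keepdims=True)
            sd = Xc.std(axis=1)
            r = (Xc @ batch) / (len(batch) * np.maximum(sd, 1e-12))
            return np.median(r**2)

        before, after = med_r2(ds.lognorm), med_r2(corrected.lognorm)
        assert after <= 0.1 * before


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

def _hvg_sim(seed, n_null=2000, n_inflated=100, n_obs=200, inflation=4.0):
    rng = np.random.default_rng(seed)
    n = n_null + n_inflated
    means = rng.uniform(1, 8, size=n)
    sd = 0.4 + 0.08 * means  # smooth mean-variance trend
    X = means[:, None] + sd[:, None] * rng.standard_normal((n, n_obs))
    X[n_null:] = means[n_null:, None] + np.sqrt(inflation) * sd[n_null:, None] * (
        rng.standard_normal((n_inflated, n_obs))
    )
    obs = pd.DataFrame(
        {"cell_class": ["A"] * n_obs}, index=pd.Index([f"n{i}" for i in range(n_obs)])
    )
    ds = ExpressionDataset(
        counts=np.zeros((n, n_obs), dtype=int), genes=gene_index(n), obs=obs
    )
    ds.lognorm = X
    truth = np.zeros(n, dtype=bool)
    truth[n_null:] = True
    return ds, truth


class TestHVG:
    def test_inflated_genes_found_with_controlled_fdr(self):
        """>= 80% of 4x-inflated genes selected and empirical FDR among
        trend-following genes <= 2x nominal, pooled over 10 seeds."""
        tp = fp = total_inflated = 0
        for seed in range(10):
            ds, truth = _hvg_sim(seed)
            res = ctnet.select_hvgs(ds, fdr=0.1)
            sel = res.table["selected"].to_numpy()
            tp += int((sel & truth).sum())
            fp += int((sel & ~truth).sum())
            total_inflated += int(truth.sum())
        assert tp / total_inflated >= 0.8
        assert fp / max(tp + fp, 1) <= 0.2

    def test_constant_gene_never_selected(self):
        ds, _ = _hvg_sim(0, n_null=50, n_inflated=5, n_obs=100)
        ds.lognorm[0] = 3.0
        res = ctnet.select_hvgs(ds)
        row = res.table.iloc[0]
        assert row["bio"] <= 0 and not row["selected"]

    def test_selection_invariant_to_gene_order(self):
        ds, _ = _hvg_sim(1, n_null=300, n_inflated=30)
        res = ctnet.select_hvgs(ds)
        perm = np.random.default_rng(0).permutation(ds.n_genes)
        shuffled = ExpressionDataset(
            counts=ds.counts[perm], genes=ds.genes[perm], obs=ds.obs
        )
        shuffled.lognorm = ds.lognorm[perm]
        res2 = ctnet.select_hvgs(shuffled)
        assert set(res.selected_genes) == set(res2.selected_genes)

    def test_too_few_genes_raises(self):
        ds, _ = _hvg_sim(0, n_null=5, n_inflated=0)
        with pytest.raises(ValueError, match="10 genes"):
            ctnet.select_hvgs(ds)
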