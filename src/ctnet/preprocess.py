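"""Quality control, normalisation, batch adjustment and HVG selection.

These are deliberately simple, documented re-implementations of the usual
snRNA-seq preprocessing stack:

* MAD-based lower-tail QC on log library size and log detected genes;
* library-size factor normalisation (factors rescaled to mean 1) with
  ``log2(x + 1)`` transform;
* parametric empirical-Bayes location/scale batch correction (the ComBat
  model: standardise per gene, shrink per-batch gene means and variances
  across genes, adjust, restore);
* highly-variable-gene selection by decomposing per-gene variance of the
  log-normalised matrix against a running-median mean-variance trend and
  testing the biological component (variance minus trend) against zero
  with a one-sided z-test and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    dataset: ExpressionDataset,
    n_mads: float = 3.0,
    exclude_genes: list[str] | None = None,
) -> ExpressionDataset:
    """Remove low-quality nuclei and excluded / never-expressed genes.

    A nucleus is removed when its log library size or its log detected-gene
    count lies more than ``n_mads`` median absolute deviations below the
    respective median (lower tail only — unusually deep nuclei are kept).
    Genes listed in ``exclude_genes`` (e.g. mitochondrial genes) and genes
    detected in zero nuclei are dropped.
    """
    lib = dataset.library_sizes()
    detected = (dataset.counts > 0).sum(axis=0).astype(float)

    def lower_outlier(values: np.ndarray) -> np.ndarray:
        logv = np.log1p(values)
        med = np.median(logv)
        # 1.4826 makes the MAD consistent with the normal sigma
        mad = 1.4826 * np.median(np.abs(logv - med))
        if mad == 0:
            return values == 0
        return logv < med - n_mads * mad

    bad_lib = lower_outlier(lib)
    bad_det = lower_outlier(detected)
    keep_nuclei = ~(bad_lib | bad_det)
    if not keep_nuclei.any():
        raise ValueError(
            "QC removed every nucleus; review n_mads or the input matrix"
        )

    exclude = set(exclude_genes or [])
    excluded_mask = dataset.genes.isin(exclude)
    kept = dataset.subset(nucleus_mask=keep_nuclei)
    zero_mask = kept.counts.sum(axis=1) == 0
    keep_genes = ~(excluded_mask | zero_mask)
    out = kept.subset(gene_mask=keep_genes)
    out.log.append(
        "qc_filter: removed %d nuclei (lib-size rule %d, detected rule %d); "
        "removed %d genes (%d excluded, %d all-zero)"
        % (
            int((~keep_nuclei).sum()),
            int(bad_lib.sum()),
            int(bad_det.sum()),
            int((~keep_genes).sum()),
            int(excluded_mask.sum()),
            int((zero_mask & ~excluded_mask).sum()),
        )
    )
    logger.info(out.log[-1])
    return out


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def size_factors(dataset: ExpressionDataset) -> np.ndarray:
    """Library-size factors rescaled to mean 1."""
    lib = dataset.library_sizes()
    if np.any(lib == 0):
        raise ValueError("zero library size encountered; run qc_filter first")
    return lib / lib.mean()


def size_factor_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Fill ``lognorm`` with log2(count / size_factor + 1).

    Size factors are library sizes divided by their mean, so the average
    rescaled library equals the mean library size and the factors average
    exactly 1.
    """
    sf = size_factors(dataset)
    out = dataset.copy()
    out.lognorm = np.log2(dataset.counts / sf[None, :] + 1.0)
    out.log.append("size_factor_normalize: factors mean 1, range [%.3g, %.3g]" % (sf.min(), sf.max()))
    return out


def cpm(dataset: ExpressionDataset) -> np.ndarray:
    """Counts per million; every column sums to 1e6."""
    lib = dataset.library_sizes()
    if np.any(lib == 0):
        raise ValueError("zero library size encountered; run qc_filter first")
    return dataset.counts * (1e6 / lib[None, :])


# ---------------------------------------------------------------------------
# ComBat-style batch correction
# ---------------------------------------------------------------------------

def _postmean(ghat, gbar, n, dsq, t2):
    return (t2 * n * ghat + dsq * gbar) / (t2 * n + dsq)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_solve(sdat, ghat, dhat, gbar, t2, a, b, conv=1e-4, max_iter=100):
    """Standard ComBat iterative EB posterior updates for one batch."""
    n = (~np.isnan(sdat)).sum(axis=1)
    g_old, d_old = ghat.copy(), dhat.copy()
    for _ in range(max_iter):
        g_new = _postmean(ghat, gbar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def correct_batch(dataset: ExpressionDataset, batch_key: str = "batch") -> ExpressionDataset:
    """Parametric empirical-Bayes location/scale batch adjustment of lognorm."""
    if dataset.lognorm is None:
        raise ValueError("lognorm not filled; run size_factor_normalize first")
    if batch_key not in dataset.obs.columns:
        raise ValueError(f"no {batch_key!r} column in annotations")
    batches = dataset.obs[batch_key].to_numpy()
    levels = list(pd.unique(batches))
    out = dataset.copy()
    if len(levels) == 1:
        out.log.append("correct_batch: single batch, nothing to correct")
        logger.info(out.log[-1])
        return out
    counts_per = {b: int((batches == b).sum()) for b in levels}
    small = [b for b, n in counts_per.items() if n < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 nuclei: {small}")

    X = dataset.lognorm
    n_genes, n_nuclei = X.shape
    idx = {b: np.flatnonzero(batches == b) for b in levels}
    n_b = np.array([len(idx[b]) for b in levels], dtype=float)

    batch_means = {b: X[:, idx[b]].mean(axis=1) for b in levels}
    grand_mean = sum((n_b[i] / n_nuclei) * batch_means[b] for i, b in enumerate(levels))
    # pooled variance of residuals about the per-batch means (the batch
    # location effects must not inflate the standardisation scale)
    resid = X.copy()
    for b in levels:
        resid[:, idx[b]] -= batch_means[b][:, None]
    pooled_var = (resid**2).mean(axis=1)
    pooled_var = np.maximum(pooled_var, 1e-12)
    sdat = (X - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    adjusted = sdat.copy()
    for i, b in enumerate(levels):
        sub = sdat[:, idx[b]]
        ghat = sub.mean(axis=1)
        dhat = sub.var(axis=1, ddof=1)
        gbar, t2 = ghat.mean(), ghat.var(ddof=1)
        dbar, s2 = dhat.mean(), dhat.var(ddof=1)
        # method-of-moments inverse-gamma hyperpriors
        a = (2 * s2 + dbar**2) / s2
        bprior = (dbar * s2 + dbar**3) / s2
        g_star, d_star = _it_solve(sub, ghat, dhat, gbar, t2, a, bprior)
        adjusted[:, idx[b]] = (sub - g_star[:, None]) / np.sqrt(np.maximum(d_star, 1e-12))[:, None]

    out.lognorm = adjusted * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]
    out.log.append(
        "correct_batch: EB-adjusted %d batches (%s)"
        % (len(levels), ", ".join(f"{b}:{counts_per[b]}" for b in levels))
    )
    logger.info(out.log[-1])
    return out


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

@dataclass
class HVGResult:
    """Per-gene variance decomposition against the mean-variance trend."""

    table: pd.DataFrame  # gene, mean, total_var, trend, bio, p, fdr, selected

    @property
    def selected_genes(self) -> pd.Index:
        return pd.Index(self.table.loc[self.table["selected"], "gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _running_median_trend(means: np.ndarray, variances: np.ndarray, frac: float = 0.2) -> np.ndarray:
    """Robust mean-variance trend: running median over genes ordered by mean."""
    order = np.argsort(means, kind="stable")
    v_sorted = variances[order]
    n = len(means)
    half = max(15, int(frac * n / 2))
    trend_sorted = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        trend_sorted[i] = np.median(v_sorted[lo:hi])
    trend = np.empty(n)
    trend[order] = trend_sorted
    return trend


def select_hvgs(dataset: ExpressionDataset, fdr: float = 0.1) -> HVGResult:
    """Select genes whose variance exceeds the technical trend.

    Biological component = total variance - trend value at the gene's mean.
    Under approximate normality of log-expression the sample variance of a
    trend-following gene has standard deviation ``trend * sqrt(2/(n-1))``;
    the one-sided z-test of ``bio > 0`` is BH-corrected and genes with
    adjusted p below ``fdr`` (and positive bio) are selected.
    """
    if dataset.lognorm is None:
        raise ValueError("lognorm not filled; run size_factor_normalize first")
    X = dataset.lognorm
    n_genes, n_nuclei = X.shape
    if n_genes < 10:
        raise ValueError("fewer than 10 genes; mean-variance trend unfittable")
    means = X.mean(axis=1)
    total_var = X.var(axis=1, ddof=1)
    trend = _running_median_trend(means, total_var)
    trend = np.maximum(trend, 1e-12)
    bio = total_var - trend
    z = bio / (trend * np.sqrt(2.0 / (n_nuclei - 1)))
    p = stats.norm.sf(z)
    q = bh_adjust(p)
    selected = (q < fdr) & (bio > 0)
    table = pd.DataFrame(
        {
            "gene": dataset.genes,
            "mean": means,
            "total_var": total_var,
            "trend": trend,
            "bio": bio,
            "p": p,
            "fdr": q,
            "selected": selected,
        }
    )
    logger.info("select_hvgs: %d of %d genes selected at FDR %.3g", int(selected.sum()), n_genes, fdr)
    return HVGResult(table=table)
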