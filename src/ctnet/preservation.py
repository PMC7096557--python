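"""Permutation-based module preservation (Zsummary) between networks.

A module found in a reference cell type's network is "preserved" in a
test cell type when its density and connectivity patterns reappear there.
Three statistics are used:

* density: mean off-diagonal adjacency among the module genes in the test
  network;
* cor_kim: Pearson correlation between the intramodular connectivity
  vectors (within-module adjacency row sums) computed in the reference
  and the test network;
* cor_cor: Pearson correlation between the vectorised upper-triangle
  within-module correlation entries of the two networks.

Each statistic is standardised against a permutation null of random gene
sets of the same size drawn from the shared gene universe (the
intersection of the two networks' gene lists). Zdensity is the density Z;
Zconnectivity is the median of the two connectivity Zs; Zsummary is their
mean. Zsummary below 2 is read as no evidence of preservation — for a
module claimed to be specific to its own cell type, the *median* Zsummary
across all other cell types' networks must stay below 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork

STATS = ("density", "cor_kim", "cor_cor")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(
    cor_ref: np.ndarray, cor_test: np.ndarray, beta_ref: int, beta_test: int
) -> dict[str, float]:
    """The three preservation statistics for one gene-set submatrix pair."""
    a_test = np.abs(cor_test) ** beta_test
    np.fill_diagonal(a_test, 0.0)
    a_ref = np.abs(cor_ref) ** beta_ref
    np.fill_diagonal(a_ref, 0.0)
    m = cor_ref.shape[0]
    density = float(a_test.sum() / (m * (m - 1)))
    kim_ref = a_ref.sum(axis=1)
    kim_test = a_test.sum(axis=1)
    iu = np.triu_indices(m, k=1)
    return {
        "density": density,
        "cor_kim": _pearson(kim_ref, kim_test),
        "cor_cor": _pearson(cor_ref[iu], cor_test[iu]),
    }


def _shared_index(
    ref: CoexpressionNetwork, test: CoexpressionNetwork
) -> tuple[list[str], dict[str, int], dict[str, int]]:
    shared = sorted(set(ref.genes) & set(test.genes))
    ref_pos = {g: i for i, g in enumerate(ref.genes)}
    test_pos = {g: i for i, g in enumerate(test.genes)}
    return shared, ref_pos, test_pos


def preservation_stats(
    ref: CoexpressionNetwork,
    test: CoexpressionNetwork,
    module_genes,
) -> dict[str, float | bool | int]:
    """Observed preservation statistics of a module between two networks.

    Module genes are intersected with both networks' gene universes;
    fewer than 3 shared genes makes the statistics undefined and the
    result is flagged not-evaluable.
    """
    shared, ref_pos, test_pos = _shared_index(ref, test)
    shared_set = set(shared)
    module = [g for g in dict.fromkeys(module_genes) if g in shared_set]
    if len(module) < 3:
        return {"evaluable": False, "n_genes": len(module)}
    ri = np.array([ref_pos[g] for g in module])
    ti = np.array([test_pos[g] for g in module])
    stats = _module_stats(
        ref.cor[np.ix_(ri, ri)], test.cor[np.ix_(ti, ti)], ref.beta, test.beta
    )
    stats.update({"evaluable": True, "n_genes": len(module)})
    return stats


@dataclass
class ZsummaryResult:
    """Permutation Z scores of one (module, test network) comparison."""

    observed: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    z: dict[str, float]
    zdensity: float
    zconnectivity: float
    zsummary: float
    n_perm: int
    n_genes: int
    seed: int
    evaluable: bool


def zsummary(
    ref: CoexpressionNetwork,
    test: CoexpressionNetwork,
    module_genes,
    n_perm: int = 100,
    seed: int = 0,
) -> ZsummaryResult:
    """Permutation Zsummary of a module from ``ref`` evaluated in ``test``.

    The null draws ``n_perm`` random gene sets of the module's size from
    the shared gene universe; each statistic's Z is (observed - null mean)
    / null sd. Deterministic under a fixed seed. A zero null sd (or a
    module with < 3 shared genes) flags the result not-evaluable.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50 for a usable null")
    shared, ref_pos, test_pos = _shared_index(ref, test)
    shared_set = set(shared)
    module = [g for g in dict.fromkeys(module_genes) if g in shared_set]
    not_eval = ZsummaryResult(
        observed={}, null_mean={}, null_sd={}, z={},
        zdensity=np.nan, zconnectivity=np.nan, zsummary=np.nan,
        n_perm=n_perm, n_genes=len(module), seed=seed, evaluable=False,
    )
    if len(module) < 3:
        return not_eval
    m = len(module)
    ri = np.array([ref_pos[g] for g in module])
    ti = np.array([test_pos[g] for g in module])
    observed = _module_stats(
        ref.cor[np.ix_(ri, ri)], test.cor[np.ix_(ti, ti)], ref.beta, test.beta
    )

    rng = np.random.default_rng(seed)
    ref_all = np.array([ref_pos[g] for g in shared])
    test_all = np.array([test_pos[g] for g in shared])
    null = {s: np.empty(n_perm) for s in STATS}
    for it in range(n_perm):
        pick = rng.choice(len(shared), size=m, replace=False)
        rr, tt = ref_all[pick], test_all[pick]
        stats = _module_stats(
            ref.cor[np.ix_(rr, rr)], test.cor[np.ix_(tt, tt)], ref.beta, test.beta
        )
        for s in STATS:
            null[s][it] = stats[s]

    null_mean, null_sd, z = {}, {}, {}
    for s in STATS:
        vals = null[s]
        valid = vals[np.isfinite(vals)]
        if valid.size < 0.8 * n_perm:
            return not_eval
        null_mean[s] = float(valid.mean())
        null_sd[s] = float(valid.std(ddof=1))
        if null_sd[s] == 0 or not np.isfinite(observed[s]):
            return not_eval
        z[s] = (observed[s] - null_mean[s]) / null_sd[s]

    zdensity = z["density"]
    zconnectivity = float(np.median([z["cor_kim"], z["cor_cor"]]))
    return ZsummaryResult(
        observed=observed, null_mean=null_mean, null_sd=null_sd, z=z,
        zdensity=zdensity, zconnectivity=zconnectivity,
        zsummary=0.5 * (zdensity + zconnectivity),
        n_perm=n_perm, n_genes=m, seed=seed, evaluable=True,
    )


def median_zsummary(zsummaries) -> tuple[float, int]:
    """Median Zsummary over evaluable test networks.

    Returns ``(median, n_not_evaluable)``; the median is NaN (verdict
    "undetermined") when no test network was evaluable.
    """
    values = [r.zsummary for r in zsummaries if r.evaluable]
    n_bad = sum(1 for r in zsummaries if not r.evaluable)
    if not values:
        return np.nan, n_bad
    return float(np.median(values)), n_bad


def preservation_report(
    networks: dict[str, CoexpressionNetwork],
    module_sets,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Zsummary of every module against every other cell type's network.

    ``module_sets`` maps module name -> (cell class, gene list). One row
    per (module, test network); per-module seeds are derived from the root
    seed deterministically.
    """
    rows = []
    for k, (module, (cls, genes)) in enumerate(sorted(module_sets.items())):
        ref = networks[cls]
        for j, (other, test_net) in enumerate(sorted(networks.items())):
            if other == cls:
                continue
            sub_seed = (seed + 100003 * k + 1009 * j) % (2**31 - 1)
            res = zsummary(ref, test_net, genes, n_perm=n_perm, seed=sub_seed)
            rows.append(
                {
                    "module": module,
                    "cell_class": cls,
                    "test_network": other,
                    "n_genes": res.n_genes,
                    "density": res.observed.get("density", np.nan),
                    "z_density": res.zdensity,
                    "z_cor_kim": res.z.get("cor_kim", np.nan),
                    "z_cor_cor": res.z.get("cor_cor", np.nan),
                    "z_connectivity": res.zconnectivity,
                    "zsummary": res.zsummary,
                    "evaluable": res.evaluable,
                }
            )
    return pd.DataFrame(rows)


def summarize_preservation(report: pd.DataFrame, zsummary_cutoff: float = 2.0) -> pd.DataFrame:
    """Per-module median Zsummary and the specificity verdict."""
    rows = []
    for module, sub in report.groupby("module", sort=True):
        ok = sub[sub["evaluable"]]
        med = float(ok["zsummary"].median()) if len(ok) else np.nan
        rows.append(
            {
                "module": module,
                "cell_class": sub["cell_class"].iloc[0],
                "median_zsummary": med,
                "n_test_networks": len(sub),
                "n_not_evaluable": int((~sub["evaluable"]).sum()),
                "verdict": (
                    "undetermined" if np.isnan(med)
                    else ("specific" if med < zsummary_cutoff else "preserved")
                ),
            }
        )
    return pd.DataFrame(rows)
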