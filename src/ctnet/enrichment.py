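"""Over-representation tests and the module selection logic.

Hypergeometric upper-tail tests of gene-set overlap against a fixed
universe, Benjamini-Hochberg FDR correction (one family per gene set,
across all modules of a run), the three-filter candidate rule (disease
enrichment AND own-class marker enrichment AND no other-class marker
enrichment), and the final verdict that additionally requires a median
preservation Zsummary below the cutoff (low Zsummary = the module is not
preserved in other cell types, i.e. it is cell type-specific).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_test(
    module_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of module / gene-set overlap.

    Returns ``(x, p)`` with ``x`` the overlap size and ``p`` the
    probability of an overlap at least that large when ``n`` module genes
    are drawn without replacement from a universe of ``N`` genes of which
    ``K`` belong to the set. Genes of the set outside the universe are
    dropped (and logged); a module gene outside the universe is an error,
    because it signals a universe mismatch upstream.
    """
    universe = set(universe)
    module = set(module_genes)
    outside = module - universe
    if outside:
        raise ValueError(
            f"module genes absent from the universe: {sorted(outside)[:5]}"
        )
    full_set = set(gene_set)
    in_universe = full_set & universe
    if len(in_universe) < len(full_set):
        logger.debug(
            "hypergeom_test: %d of %d set genes outside the universe dropped",
            len(full_set) - len(in_universe), len(full_set),
        )
    N, K, n = len(universe), len(in_universe), len(module)
    x = len(module & in_universe)
    # survival function at x-1 gives P(X >= x); exact and log-space safe
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return x, min(p, 1.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GMT parsing
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into ``{name: (description, genes)}``."""
    collection: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line (need name, description, >=1 gene)"
            )
        name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: GMT term {name!r} lists no genes")
        collection[name] = (description, frozenset(genes))
    return collection


# ---------------------------------------------------------------------------
# Enrichment tables
# ---------------------------------------------------------------------------

def enrichment_matrix(
    module_sets: Mapping[str, Iterable[str]],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Test every (module, gene set) pair; BH per gene-set family.

    The family of each BH correction is one gene set across all modules of
    the run (the most conservative reading of a per-column FDR). Gene sets
    that are empty after intersection with the universe yield rows flagged
    ``evaluable = False`` with p and q of NaN.
    """
    universe = list(universe)
    uni_set = set(universe)
    rows = []
    for set_name, genes in gene_sets.items():
        set_in_uni = set(genes) & uni_set
        for mod_name, mod_genes in module_sets.items():
            mod = set(mod_genes)
            if set_in_uni:
                x, p = hypergeom_test(mod, set_in_uni, uni_set)
                evaluable = True
            else:
                x, p, evaluable = 0, np.nan, False
            rows.append(
                {
                    "module": mod_name,
                    "gene_set": set_name,
                    "module_size": len(mod),
                    "universe_size": len(uni_set),
                    "set_size": len(set_in_uni),
                    "overlap": x,
                    "p": p,
                    "evaluable": evaluable,
                    "overlap_genes": ",".join(sorted(mod & set_in_uni)),
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for set_name in gene_sets:
        mask = (table["gene_set"] == set_name) & table["evaluable"]
        if mask.any():
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"])
    table["enriched"] = table["evaluable"] & (table["q"] < alpha)
    return table


def annotate_modules_gmt(
    module_sets: Mapping[str, Iterable[str]],
    gmt_collection: Mapping[str, tuple[str, frozenset[str]]],
    universe: Iterable[str],
    alpha: float = 0.1,
    min_genes: int = 5,
    min_genes_on: str = "overlap",
) -> pd.DataFrame:
    """Functional annotation of modules against a GMT collection.

    Every (module, term) pair is tested; the returned table carries a
    ``reported`` flag for rows with q below ``alpha`` and a gene count of
    at least ``min_genes``. ``min_genes_on`` selects whether that count is
    the module/term overlap (default) or the term size within the universe
    (``"term"``).
    """
    if min_genes_on not in ("overlap", "term"):
        raise ValueError("min_genes_on must be 'overlap' or 'term'")
    if not gmt_collection:
        logger.warning("annotate_modules_gmt: empty GMT collection")
        return pd.DataFrame(
            columns=[
                "module", "gene_set", "description", "module_size", "universe_size",
                "set_size", "overlap", "p", "evaluable", "overlap_genes", "q", "reported",
            ]
        )
    gene_sets = {name: genes for name, (_, genes) in gmt_collection.items()}
    table = enrichment_matrix(module_sets, gene_sets, universe, alpha=alpha)
    table["description"] = table["gene_set"].map(
        {name: desc for name, (desc, _) in gmt_collection.items()}
    )
    count = table["overlap"] if min_genes_on == "overlap" else table["set_size"]
    table["reported"] = table["evaluable"] & (table["q"] < alpha) & (count >= min_genes)
    return table


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_modules(
    enrichment_table: pd.DataFrame,
    module_class: Mapping[str, str],
    disease_set: str,
    marker_set_of_class: Mapping[str, str],
    median_zsummary: Mapping[str, float],
    alpha: float = 0.1,
    zsummary_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Apply the three-filter candidate rule and the preservation filter.

    candidate  = disease-enriched AND own-class-marker-enriched AND not
                 enriched with any other class's markers (all at q < alpha);
    final      = candidate AND median Zsummary < cutoff (no evidence the
                 module is preserved in the other cell types).

    A candidate without an evaluable preservation median gets status
    ``undetermined``.
    """
    q = enrichment_table.pivot_table(index="module", columns="gene_set", values="q")
    rows = []
    for module, cls in module_class.items():
        own_set = marker_set_of_class.get(cls)
        if own_set is None:
            raise ValueError(f"no marker panel for cell class {cls!r}")
        qrow = q.loc[module] if module in q.index else pd.Series(dtype=float)

        def q_of(set_name: str) -> float:
            val = qrow.get(set_name, np.nan)
            return float(val) if pd.notna(val) else np.nan

        asd_q = q_of(disease_set)
        own_q = q_of(own_set)
        other_qs = {
            c: q_of(s) for c, s in marker_set_of_class.items() if s != own_set
        }
        asd_enriched = bool(asd_q < alpha) if not np.isnan(asd_q) else False
        own_enriched = bool(own_q < alpha) if not np.isnan(own_q) else False
        other_enriched = any(
            (not np.isnan(v)) and v < alpha for v in other_qs.values()
        )
        candidate = asd_enriched and own_enriched and not other_enriched
        mz = median_zsummary.get(module, np.nan)
        mz = float(mz) if mz is not None else np.nan
        if candidate and np.isnan(mz):
            status, final = "undetermined", False
        else:
            status = "ok"
            final = bool(candidate and mz < zsummary_cutoff)
        rows.append(
            {
                "module": module,
                "cell_class": cls,
                "disease_q": asd_q,
                "own_marker_q": own_q,
                "min_other_marker_q": (
                    np.nanmin(list(other_qs.values())) if other_qs else np.nan
                ),
                "asd_enriched": asd_enriched,
                "own_marker_enriched": own_enriched,
                "other_marker_enriched": other_enriched,
                "candidate": candidate,
                "median_zsummary": mz,
                "final_specific": final,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
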