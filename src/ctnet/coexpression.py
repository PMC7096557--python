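"""Weighted co-expression networks and module detection for one cell type.

Pipeline for a single cell type's expression submatrix:

    Pearson correlation -> unsigned adjacency |r|^beta -> signed TOM
    -> average-linkage clustering of 1 - TOM -> adaptive branch cut
    -> module eigengenes -> eigengene-correlation merging -> kME pruning
    -> optional hub-gene network export.

The topological overlap matrix follows the signed convention: neighbour
products carry the correlation signs, and the numerator takes the absolute
value, so genes whose shared neighbours agree in sign overlap strongly
while sign-discordant neighbourhoods cancel.

The branch cut is a simplified dynamic tree cut: merge heights are
min-max normalised and the tree is cut just below its top (default at
0.998 of the height range — on a TOM dendrogram uncorrelated genes merge
essentially at the maximum height, so the branches below the cut are the
candidate modules). A branch becomes a module when it holds at least
``min_module_size`` genes and is cohesive: its mean within-branch TOM
must exceed a multiple of the network's median topological overlap, so
loose aggregates of background genes are rejected and pure-noise
networks yield no modules at all. Inside an accepted branch, a
``deep_split``-dependent height-gap rule recursively splits off tight
sub-branches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: attachment-gap threshold (on the normalised height scale) per deep_split
DEEP_SPLIT_GAP = {0: 0.35, 1: 0.25, 2: 0.15, 3: 0.10, 4: 0.05}

FALLBACK_POWER = 6


# ---------------------------------------------------------------------------
# correlation / adjacency / TOM
# ---------------------------------------------------------------------------

def correlation_matrix(X: np.ndarray, cell_type: str | None = None) -> np.ndarray:
    """Pearson correlation between the rows (genes) of X.

    Requires >= 3 columns (nuclei) and no zero-variance rows; symmetric
    output with an exact unit diagonal.
    """
    X = np.asarray(X, dtype=float)
    label = f" for cell type {cell_type!r}" if cell_type else ""
    if X.shape[1] < 3:
        raise ValueError(f"need >= 3 nuclei to correlate genes{label}, got {X.shape[1]}")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"{int((sd == 0).sum())} zero-variance genes present{label}; remove them first"
        )
    cor = np.corrcoef(X)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned weighted adjacency A_ij = |cor_ij|^beta, unit diagonal."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    A = np.abs(cor) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def signed_tom(A: np.ndarray, cor: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix.

    TOM_ij = |l_ij + s_ij a_ij| / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_u s_iu a_iu s_uj a_uj over u != i, j, s = sign(cor),
    a = |cor|^beta and k_i the (diagonal-free) connectivity. Diagonal 1.
    """
    A = np.asarray(A, dtype=float)
    cor = np.asarray(cor, dtype=float)
    if A.shape != cor.shape or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency and correlation must be square and conformable")
    if not np.allclose(A, A.T, atol=1e-10) or not np.allclose(cor, cor.T, atol=1e-10):
        raise ValueError("adjacency and correlation must be symmetric")
    S = np.sign(cor) * A
    np.fill_diagonal(S, 0.0)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = S @ S  # (i,j): sum_u s_iu a_iu s_uj a_uj, u ranging over all but i, j via zero diag
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    tom = np.abs(L + S) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# soft-threshold selection
# ---------------------------------------------------------------------------

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of the log-log scale-free topology fit of connectivities."""
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) < 1e-12:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return np.nan, np.nan
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - yhat) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return r2, slope


def pick_soft_threshold(
    cor: np.ndarray,
    candidate_powers=range(1, 21),
    r2_target: float = 0.8,
) -> int:
    """Smallest power whose connectivity distribution fits a scale-free law.

    For each candidate beta the connectivities k_i = sum_{j != i} |r_ij|^beta
    are binned and log10 p(k) is regressed on log10 k; the smallest beta
    with R^2 >= ``r2_target`` and a negative slope wins. If none qualifies
    (or the connectivities are degenerate) the conventional fallback power
    6 is returned with a warning.
    """
    abs_cor = np.abs(np.asarray(cor, dtype=float))
    np.fill_diagonal(abs_cor, 0.0)
    for beta in candidate_powers:
        k = (abs_cor**beta).sum(axis=1)
        if k.std() < 1e-10 * max(k.mean(), 1e-30):
            break  # all-equal connectivities: scale-free fit undefined
        r2, slope = scale_free_fit(k)
        if np.isfinite(r2) and r2 >= r2_target and slope < 0:
            return int(beta)
    warnings.warn(
        f"no candidate power reached scale-free R^2 {r2_target:g}; "
        f"falling back to beta = {FALLBACK_POWER}",
        stacklevel=2,
    )
    return FALLBACK_POWER


# ---------------------------------------------------------------------------
# module detection (simplified dynamic tree cut)
# ---------------------------------------------------------------------------

#: a module's mean within-branch TOM must exceed this multiple of the
#: network-wide median topological overlap
COHESION_RATIO = 5.0


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_fraction: float = 0.998,
) -> np.ndarray:
    """Cluster 1 - TOM by average linkage and cut branches adaptively.

    Returns an integer label per gene; 0 means unassigned. Modules are
    numbered 1.. in decreasing size (ties broken by smallest member index).
    """
    if deep_split not in DEEP_SPLIT_GAP:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_GAP)}")
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn(
            f"{n} genes < min_module_size {min_module_size}: no modules", stacklevel=2
        )
        return np.zeros(n, dtype=int)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.average(squareform(diss, checks=False))
    return _cut_tree(Z, tom, min_module_size, DEEP_SPLIT_GAP[deep_split], cut_fraction)


def _cut_tree(
    Z: np.ndarray, tom: np.ndarray, min_size: int, gap: float, cut_fraction: float
) -> np.ndarray:
    n = tom.shape[0]
    heights = Z[:, 2]
    h_min, h_max = heights.min(), heights.max()
    if h_max - h_min < 1e-12:
        return np.zeros(n, dtype=int)
    cut = h_min + cut_fraction * (h_max - h_min)

    # node k < n is a leaf; node n + i is the merge on row i of Z
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    size = np.ones(2 * n - 1, dtype=int)
    height = np.zeros(2 * n - 1)
    parent_height = np.full(2 * n - 1, np.inf)
    for i in range(n - 1):
        size[n + i] = size[left[i]] + size[right[i]]
        height[n + i] = heights[i]
        parent_height[left[i]] = heights[i]
        parent_height[right[i]] = heights[i]

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((left[v - n], right[v - n]))
        return out

    def subtree_min_height(node: int) -> float:
        if node < n:
            return height[node]
        best, stack = np.inf, [node]
        while stack:
            v = stack.pop()
            if v >= n:
                best = min(best, height[v])
                stack.extend((left[v - n], right[v - n]))
        return best

    modules: list[list[int]] = []

    def refine(node: int) -> None:
        """Deep split inside an accepted branch, on its own height scale."""
        if node >= n:
            lo = subtree_min_height(node)
            span = height[node] - lo
            l, r = left[node - n], right[node - n]
            if (
                span > 1e-12
                and size[l] >= min_size
                and size[r] >= min_size
                and (height[node] - height[l]) / span >= gap
                and (height[node] - height[r]) / span >= gap
            ):
                refine(l)
                refine(r)
                return
        modules.append(leaves(node))

    iu = np.triu_indices(n, k=1)
    median_overlap = float(np.median(tom[iu]))
    floor = max(COHESION_RATIO * median_overlap, 1e-12)

    # branch roots: maximal subtrees entirely below the cut
    branch_roots = [
        v for v in range(2 * n - 1)
        if size[v] >= min_size and height[v] <= cut and parent_height[v] > cut
    ]
    for v in branch_roots:
        members = leaves(v)
        sub = tom[np.ix_(members, members)]
        within = float(sub[np.triu_indices(len(members), k=1)].mean())
        if within > floor:
            refine(v)

    labels = np.zeros(n, dtype=int)
    modules.sort(key=lambda m: (-len(m), min(m)))
    for lab, members in enumerate(modules, start=1):
        labels[members] = lab
    return labels


# ---------------------------------------------------------------------------
# eigengenes, merging, kME
# ---------------------------------------------------------------------------

def module_eigengene(
    X: np.ndarray, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First-PC eigengene (per nucleus) and variance explained per module.

    Genes are standardised across nuclei before the PCA; eigengenes are
    unit-norm and oriented to correlate positively with the module's mean
    standardised expression. Zero-variance genes are dropped with a notice.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    eigengenes: dict[int, np.ndarray] = {}
    varexpl: dict[int, float] = {}
    for lab in sorted(set(labels) - {0}):
        rows = np.flatnonzero(labels == lab)
        sub = X[rows]
        sd = sub.std(axis=1)
        if np.any(sd == 0):
            logger.info(
                "module %d: dropping %d zero-variance genes from PCA", lab, int((sd == 0).sum())
            )
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError(f"module {lab} has fewer than 2 usable genes")
        Xs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(Xs, full_matrices=False)
        eg = vt[0]
        mean_profile = Xs.mean(axis=0)
        if np.dot(eg, mean_profile) < 0:
            eg = -eg
        eigengenes[lab] = eg
        varexpl[lab] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(eigengenes)
    frame.columns = [f"ME{lab}" for lab in eigengenes]
    return frame, varexpl


def merge_modules(
    X: np.ndarray,
    labels: np.ndarray,
    merge_cut_height: float = 0.2,
) -> np.ndarray:
    """Merge modules whose eigengenes cluster below ``merge_cut_height``.

    Eigengene dissimilarity is 1 - cor; average-linkage clusters with
    linkage height strictly below the cut are merged, eigengenes are
    recomputed, and the process repeats until stable.
    """
    labels = np.asarray(labels).copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eigengenes, _ = module_eigengene(X, labels)
        E = eigengenes.to_numpy().T  # modules x nuclei
        diss = 1.0 - np.corrcoef(E)
        np.fill_diagonal(diss, 0.0)
        Z = hierarchy.average(squareform(np.clip(diss, 0, 2), checks=False))
        groups = hierarchy.fcluster(Z, t=np.nextafter(merge_cut_height, 0), criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mapping: dict[int, int] = {}
        for lab, grp in zip(mods, groups):
            mapping[lab] = grp
        labels = np.array([mapping.get(lab, 0) for lab in labels])
        labels = _relabel_by_size(labels)
    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    mods = sorted(
        set(labels) - {0},
        key=lambda lab: (-int((labels == lab).sum()), int(np.flatnonzero(labels == lab)[0])),
    )
    mapping = {old: new for new, old in enumerate(mods, start=1)}
    return np.array([mapping.get(lab, 0) for lab in labels], dtype=int)


def kme_table(X: np.ndarray, eigengenes: pd.DataFrame) -> np.ndarray:
    """Gene x module matrix of correlations with the module eigengenes."""
    X = np.asarray(X, dtype=float)
    E = eigengenes.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=0, keepdims=True)
    x_sd = np.sqrt((Xc**2).sum(axis=1))
    e_sd = np.sqrt((Ec**2).sum(axis=0))
    x_sd[x_sd == 0] = np.inf  # zero-variance gene: kME 0
    return (Xc @ Ec) / np.outer(x_sd, e_sd)


@dataclass
class ModuleSet:
    """Final module assignment with eigengenes and kME for one network."""

    genes: pd.Index
    labels: np.ndarray  # 0 = unassigned
    eigengenes: pd.DataFrame  # nuclei x modules (columns ME<label>)
    varexpl: dict[int, float]
    kme: pd.DataFrame  # genes x modules
    cell_type: str | None = None
    log: list[str] = field(default_factory=list)

    def module_labels(self) -> list[int]:
        return sorted(set(self.labels.tolist()) - {0})

    def module_genes(self, label: int) -> list[str]:
        return list(self.genes[self.labels == label])

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "module": self.labels})


def kme_prune(
    X: np.ndarray,
    genes: pd.Index,
    labels: np.ndarray,
    min_kme: float = 0.2,
    cell_type: str | None = None,
) -> ModuleSet:
    """Drop genes whose own-module |kME| falls below ``min_kme``.

    Eigengenes (and the kME table) are recomputed once after pruning.
    Modules reduced below 2 genes dissolve to unassigned.
    """
    labels = np.asarray(labels).copy()
    eigengenes, _ = module_eigengene(X, labels)
    kme = kme_table(X, eigengenes)
    col_of = {lab: j for j, lab in enumerate(int(c[2:]) for c in eigengenes.columns)}
    n_pruned = 0
    for i, lab in enumerate(labels):
        if lab == 0:
            continue
        if abs(kme[i, col_of[lab]]) < min_kme:
            labels[i] = 0
            n_pruned += 1
    for lab in list(set(labels) - {0}):
        if (labels == lab).sum() < 2:
            labels[labels == lab] = 0
    labels = _relabel_by_size(labels)
    notes = [f"kme_prune: {n_pruned} genes moved to unassigned (min_kme={min_kme})"]
    if labels.max(initial=0) == 0:
        return ModuleSet(
            genes=genes, labels=labels, eigengenes=pd.DataFrame(index=range(X.shape[1])),
            varexpl={}, kme=pd.DataFrame(index=genes), cell_type=cell_type, log=notes,
        )
    eigengenes, varexpl = module_eigengene(X, labels)
    kme = pd.DataFrame(kme_table(X, eigengenes), index=genes, columns=eigengenes.columns)
    return ModuleSet(
        genes=genes, labels=labels, eigengenes=eigengenes, varexpl=varexpl,
        kme=kme, cell_type=cell_type, log=notes,
    )


# ---------------------------------------------------------------------------
# network container and one-call detection
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """Correlation network of one cell type with derived matrices."""

    cell_type: str
    genes: pd.Index
    cor: np.ndarray
    beta: int
    _adjacency: np.ndarray | None = None
    _tom: np.ndarray | None = None

    @property
    def adjacency_matrix(self) -> np.ndarray:
        if self._adjacency is None:
            self._adjacency = adjacency(self.cor, self.beta)
        return self._adjacency

    @property
    def tom(self) -> np.ndarray:
        if self._tom is None:
            self._tom = signed_tom(self.adjacency_matrix, self.cor)
        return self._tom


def build_network(
    X: np.ndarray,
    genes: pd.Index,
    cell_type: str,
    beta: int | None = None,
    candidate_powers=range(1, 21),
    r2_target: float = 0.8,
) -> tuple[CoexpressionNetwork, np.ndarray]:
    """Correlation network for one cell type's lognorm submatrix.

    Zero-variance genes (within this cell type) are excluded from the
    network, and the expression submatrix restricted to the surviving
    genes is returned alongside.
    """
    X = np.asarray(X, dtype=float)
    keep = X.std(axis=1) > 0
    if not keep.all():
        logger.info(
            "build_network(%s): excluding %d zero-variance genes",
            cell_type, int((~keep).sum()),
        )
    X = X[keep]
    genes = pd.Index(genes)[keep]
    cor = correlation_matrix(X, cell_type=cell_type)
    if beta is None:
        beta = pick_soft_threshold(cor, candidate_powers, r2_target)
    return CoexpressionNetwork(cell_type=cell_type, genes=genes, cor=cor, beta=int(beta)), X


def detect_module_set(
    network: CoexpressionNetwork,
    X: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_cut_height: float = 0.2,
    min_kme: float = 0.2,
    kme_rescue: float = 0.3,
) -> ModuleSet:
    """detect -> merge -> kME rescue -> prune, returning the final ModuleSet.

    The rescue step plays the role of WGCNA's PAM stage: an unassigned
    gene whose best |kME| reaches ``kme_rescue`` joins that module, which
    recovers weakly-loaded module members that the branch cut left out
    while a threshold well above the noise-level kME keeps background
    genes away. Set ``kme_rescue=None`` to disable.
    """
    labels = detect_modules(network.tom, min_module_size, deep_split)
    if labels.max(initial=0) > 0:
        labels = merge_modules(X, labels, merge_cut_height)
        if kme_rescue is not None:
            eigengenes, _ = module_eigengene(X, labels)
            kme = kme_table(X, eigengenes)
            mods_order = [int(c[2:]) for c in eigengenes.columns]
            for i in np.flatnonzero(labels == 0):
                j = int(np.argmax(np.abs(kme[i])))
                if abs(kme[i, j]) >= kme_rescue:
                    labels[i] = mods_order[j]
            labels = _relabel_by_size(labels)
    if labels.max(initial=0) == 0:
        return ModuleSet(
            genes=network.genes, labels=labels,
            eigengenes=pd.DataFrame(index=range(X.shape[1])), varexpl={},
            kme=pd.DataFrame(index=network.genes), cell_type=network.cell_type,
        )
    return kme_prune(X, network.genes, labels, min_kme, cell_type=network.cell_type)


# ---------------------------------------------------------------------------
# hub export
# ---------------------------------------------------------------------------

def export_top_hub_network(
    module_set: ModuleSet,
    tom: np.ndarray,
    module_label: int,
    n: int = 50,
    edge_floor: float = 0.0,
    disease_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the top-n hub genes of one module.

    Nodes are the module's n genes of highest own-module kME (descending,
    lexicographic gene-id tie-break), annotated with kME and a
    disease-gene flag; edges are the TOM entries among them with weight
    >= ``edge_floor``, ordered by (gene_a, gene_b). Importable by
    Cytoscape.
    """
    if module_label not in module_set.module_labels():
        raise ValueError(f"module {module_label} not present")
    disease_genes = disease_genes or set()
    members = module_set.module_genes(module_label)
    col = f"ME{module_label}"
    kme = module_set.kme.loc[members, col]
    if n > len(members):
        logger.info(
            "export_top_hub_network: module %d has %d genes (< n=%d); exporting all",
            module_label, len(members), n,
        )
    ranked = sorted(members, key=lambda g: (-kme[g], g))[:n]
    pos = {g: i for i, g in enumerate(module_set.genes)}
    nodes = pd.DataFrame(
        {
            "gene": ranked,
            "kme": [float(kme[g]) for g in ranked],
            "module": module_label,
            "is_disease_gene": [g in disease_genes for g in ranked],
        }
    )
    edges = []
    for i, ga in enumerate(ranked):
        for gb in ranked[i + 1:]:
            w = float(tom[pos[ga], pos[gb]])
            if w >= edge_floor:
                a, b = sorted((ga, gb))
                edges.append({"gene_a": a, "gene_b": b, "tom_weight": w})
    edge_frame = pd.DataFrame(edges, columns=["gene_a", "gene_b", "tom_weight"])
    if len(edge_frame):
        edge_frame = edge_frame.sort_values(["gene_a", "gene_b"], ignore_index=True)
    return nodes, edge_frame
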