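# Methods

This note documents the models, statistics and numerical choices behind
`ctnet`, and what the synthetic study conditions do and do not show.

## 1. Synthetic data model

The generator (`ctnet.syndata`) emulates a single-nucleus RNA-seq
experiment at desk scale. For gene *g*, nucleus *n* of class *c* in
batch *b*:

```
counts[g, n] ~ NegativeBinomial(mean = mu[g, n], dispersion = d)
log mu[g, n] = log(base_g) + log(fold_{g,c}) + delta_{g,b}
               + sum over planted modules M containing g, active in c:
                 l_g * z_{M,n} - l_g^2 / 2
```

* `base_g` — lognormal around `baseline_mean` (default 5 counts,
  natural-log sd 0.5), the typical depth of a moderately expressed gene
  in a nuclear library of ~17,000 counts over 3,000 genes.
* `d` — a single global NB dispersion, default 0.3
  (Var = m + 0.3 m²), the simplest overdispersed law adequate for the
  rank/correlation statistics downstream.
* `fold_{g,c}` — marker up-regulation: each class carries 60 disjoint
  fold-8 markers (a strong, cleanly separable panel); genes of a
  one-class planted module additionally get fold 2 in their own class,
  because real cell type-specific modules are made of genes elevated in
  that cell type — this is what makes a module's genes rank into their
  class's specificity panel.
* `delta_{g,b} ~ N(0, batch_effect_sd)` (default 0.3 natural-log, two
  batches) — a gene-wise location shift, the family the ComBat-style
  correction removes.
* Module signal — one standard-normal latent per module and nucleus,
  entering only nuclei of the module's `active_in` classes, with
  per-gene loadings `l_g = latent_strength * u_g`, `u_g ~ U(0.5, 1.5)`.
  The loading heterogeneity gives modules the hub structure that the
  connectivity-preservation statistics measure; the `- l_g^2/2` term
  centres the lognormal factor so module membership shapes covariance,
  not the marginal mean. `latent_strength = 0.8` yields within-module
  Pearson correlations around 0.45 on the log2 scale.

Default classes: Gluta 600, GABA 300, Ast 150, Oligo 100, OPC 80 nuclei
— a strongly unbalanced layout mirroring the dominance of excitatory
neurons in cortical data while keeping each network above the
correlation-stability floor. Planted structure: an astrocyte-only
40-gene module, a 40-gene module shared by every class, a
glutamatergic-only 50-gene module, and a 150-gene disease list that
overlaps the first two modules at 20 genes each (the remaining 110 are
background genes, emulating a disease list whose bulk does not touch
any module).

**What the generator does not emulate:** dropout bursting, doublets,
ambient RNA, cell-cycle structure, UMI saturation, or gene-gene
correlation beyond the planted factors. Passing tests therefore show
the *statistical machinery* behaves as designed under an honest
overdispersed count model with planted truth — not that any particular
biological dataset will yield modules of comparable strength.

## 2. Preprocessing

* **QC** — nuclei are dropped when log1p library size or log1p detected
  genes falls more than `n_mads` (default 3) *scaled* median absolute
  deviations (MAD × 1.4826, the normal-consistent scaling) below the
  median; lower tail only. Excluded genes (e.g. a mitochondrial list)
  and all-zero genes are removed.
* **Normalisation** — library-size factors rescaled to mean 1;
  `lognorm = log2(count/sf + 1)`. This is a deliberate simplification
  of pooling-based deconvolution; the downstream statistics are
  correlations and rank-based panels, which are robust to it.
* **Batch correction** — the standard parametric empirical-Bayes
  location/scale model: per-gene standardisation about the
  batch-size-weighted grand mean and the pooled variance of residuals
  about per-batch means; per-batch gene means (normal prior) and
  variances (inverse-gamma prior, method-of-moments hyperpriors) shrunk
  by the usual iterative posterior updates (tolerance 1e-4, max 100
  iterations); adjust and restore. One batch is a logged no-op; a batch
  with < 2 nuclei is an error. An independent implementation (scanpy's
  ComBat) agrees to ~0.01 on shifted simulations.
* **HVG selection** — per-gene variance of lognorm vs a running-median
  trend over genes ordered by mean (window ≈ 20% of genes, floor 31).
  Biological component = variance − trend; under approximate normality
  the null sd of a sample variance is `trend * sqrt(2/(n−1))`, giving a
  one-sided z-test, BH-corrected at FDR 0.1. The z-test is
  anti-conservative on skewed count data (the acceptance suite checks
  calibration on Gaussian data, where empirical FDR stays within twice
  nominal); on the NB scenario it simply admits a somewhat larger
  background gene universe, which benefits the permutation null.
  Selection runs jointly across all nuclei (per-class selection is a
  flag away by subsetting).

## 3. Specificity

`specificity(g, c) = min over r != c of (mean CPM in c + eps) /
(mean CPM in r + eps)` with `eps = 1` CPM. The pseudocount guarantees
finite values when a reference class never expresses the gene; at
typical mean CPM of a few hundred it is negligible otherwise. An
"unclassified" label can be excluded from both the interest and the
reference sets (recommended: a mixed bin contaminates fold changes).
Panels are the top-`n` (default 500) genes per class, ties broken
lexicographically by gene id.

In the pipeline, specificity is computed over the **full post-QC gene
universe** by default (switchable to the HVG subset). Ranking a top-500
panel only makes sense against a universe much larger than 500; at desk
scale the HVG universe is ~450 genes, so the panel must be drawn from
all genes to retain contrast. Panels are intersected with the
enrichment universe downstream, which restores comparability. The
min-of-ratios statistic is biased slightly below 1 for uniform genes
(sampling noise enters through the minimum); the grand median for
unplanted genes sits near 0.94 under the default conditions.

## 4. Co-expression networks and modules

* Correlation: Pearson, per class, on the HVG submatrix; genes with
  zero variance *within that class* are excluded from that class's
  network only. At least 3 nuclei are required.
* Soft power: smallest beta in 1..20 whose binned log-log connectivity
  fit reaches R² ≥ 0.8 with negative slope; fallback 6 with a warning.
  Beta is chosen per class and logged in the run summary.
* Signed TOM: `TOM_ij = |l_ij + s_ij a_ij| / (min(k_i,k_j) + 1 − a_ij)`
  with `l_ij = sum_u s_iu a_iu s_uj a_uj`, `s = sign(cor)`,
  `a = |cor|^beta`. With all correlations non-negative this reduces
  exactly to the unsigned formula (tested). Values clipped to [0, 1]
  against float error.
* **Branch cut** (simplified dynamic tree cut): average linkage on
  `1 − TOM`; merge heights min-max normalised; the tree is cut at
  0.998 of the height range — on a TOM dendrogram uncorrelated genes
  merge essentially at the top, so the branches below the cut are the
  candidate modules. A branch of ≥ `min_module_size` (30) genes is kept
  only if cohesive: mean within-branch TOM > 5 × the network-wide
  median overlap. This rejects loose background aggregates; a pure
  noise network yields no modules at all, and a degenerate tree (zero
  height range) yields none either — a module is defined by contrast
  with its background. Inside an accepted branch, a deep-split rule
  recursively splits off sub-branches when both children hold
  ≥ `min_module_size` genes across a height gap ≥ a `deep_split`-
  dependent fraction (0.35/0.25/0.15/0.10/0.05 for deep_split 0–4) of
  the branch's own height range.
* Eigengenes: first right singular vector of the gene-standardised
  module submatrix (unit norm, oriented to correlate positively with
  the module's mean standardised profile); variance explained reported.
* Merging: eigengene dissimilarity `1 − cor`, average linkage, clusters
  below `merge_cut_height` (0.2) merged; iterate to a fixed point.
* **kME rescue** (the PAM-like stage): after merging, an unassigned
  gene joins the module of its best |kME| when that reaches 0.3 — well
  above the noise kME scale (~1/sqrt(n_nuclei)) — recovering weakly
  loaded module members the cut left out. Then kME pruning: genes with
  own-module |kME| < `min_kme` (0.2) are unassigned and eigengenes are
  recomputed once. The whole stage is seed-free and bit-reproducible.
* Hub export: top-`n` (50) genes by own-module kME (lexicographic
  tie-break), TOM edges ≥ `edge_floor`, Cytoscape-importable TSVs.

## 5. Module preservation (Zsummary)

Three statistics per (module, test network): density = mean off-diagonal
adjacency among module genes in the test network; cor_kim = Pearson
correlation of intramodular connectivity vectors between reference and
test; cor_cor = correlation of the vectorised upper-triangle
within-module correlations. This is a deliberate 3-statistic subset of
the published composite — the density and connectivity medians it is
defined over — kept at desk scale. The null re-draws `n_perm` (default
100; ≥ 50 enforced) random gene sets of the module's size from the
**intersection** of the two networks' gene universes (draws do not
exclude the module's own genes; the bias is negligible for modules much
smaller than the universe). `Z = (obs − null mean)/null sd`;
`Zdensity = Z[density]`; `Zconnectivity = median(Z[cor_kim],
Z[cor_cor])`; `Zsummary = (Zdensity + Zconnectivity)/2`. A zero null sd
or < 3 shared genes flags the comparison not-evaluable. The per-module
verdict uses the **median Zsummary across all evaluable test networks**:
below 2 ⇒ no evidence of preservation ⇒ cell type-specific. The
permutation null is centred (mean |Z| well inside (−0.5, 0.5), sd near
1 at n_perm = 200 under the default conditions).

## 6. Enrichment and selection

Hypergeometric upper-tail tests (exact, via the survival function)
against a fixed universe — the run's HVG list, i.e. the genes that
entered network construction. Unassigned (label 0) genes stay in the
universe but are never tested as a module. BH correction is applied
**per gene-set family across all modules of the run** (one family for
the disease list, one per marker panel, one per GMT term collection) —
the most conservative reading of a per-column FDR. A module gene absent
from the universe is an error (it signals a universe mismatch); gene-set
genes outside the universe are dropped.

Selection: `candidate = disease-enriched AND own-panel-enriched AND no
other-panel-enriched` (all at q < alpha = 0.1);
`final = candidate AND median Zsummary < 2`. A candidate without an
evaluable preservation median is reported "undetermined" rather than
silently dropped. GMT-based functional annotation reports terms with
q < 0.1 and **overlap ≥ 5 genes** ("at least five genes" is read as the
overlap; a flag switches to term-size-in-universe). No term-redundancy
removal is performed.

## 7. Pipeline, determinism, problem sizes

Classes below `min_nuclei` (default 30 — correlation estimates on fewer
nuclei are too unstable to support a network) are skipped with a logged
reason and still listed in the report. Cell-cluster-level analysis is
the same code path with the cluster label column. All randomness flows
from the config seed through named substreams (the preservation stage
derives per-(module, network) seeds deterministically), so two runs with
the same config and seed produce byte-identical TSVs; floats are written
with `%.10g`.

The test and acceptance workloads use the default scenario (3,000 genes,
1,230 nuclei, ~450 HVGs per network) and 10-seed repetitions for the
recovery/discrimination properties; these sizes keep a full suite run in
the low minutes while leaving wide margins on every planted-effect
check.

## 8. Known limitations

* The branch cut is a simplification of the published dynamic hybrid
  tree cut; agreement is assessed by planted-partition recovery, not
  label-for-label equality with WGCNA.
* A network that is one single module (no background) is reported as
  unassigned by design; the method targets modules embedded in a
  background.
* The HVG z-test leans on approximate normality of log-expression;
  heavy-tailed counts inflate its selection set (see §2).
* The scale-free power criterion can choose a low beta on
  noise-dominated networks; the cohesion rule guards module calls, but
  callers wanting WGCNA-conventional behaviour can pin `beta=6`.
* Library-size normalisation, not pooling deconvolution; no cell-cycle
  handling, imputation or doublet detection.
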