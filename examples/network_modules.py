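"""Build one cell class's weighted co-expression network and detect its
gene modules.

Pipeline: Pearson correlation -> soft threshold beta -> signed TOM ->
average-linkage clustering with an adaptive branch cut -> eigengene
merging -> kME pruning. The astrocyte network should contain two modules:
the astrocyte-only planted module and the all-class shared module.
"""

import numpy as np
import pandas as pd

import ctnet

dataset, truth = ctnet.generate_dataset(ctnet.default_config(seed=1))
pp = ctnet.correct_batch(ctnet.size_factor_normalize(ctnet.qc_filter(dataset)))
hvg = list(ctnet.select_hvgs(pp).selected_genes)
print(f"highly variable genes: {len(hvg)}")

labels = pp.obs["cell_class"].to_numpy()
cols = np.flatnonzero(labels == "Ast")
X = pp.lognorm[np.ix_(pp.genes.get_indexer(hvg), cols)]
network, X = ctnet.build_network(X, pd.Index(hvg), cell_type="Ast")
print(f"astrocyte network: {len(network.genes)} genes, soft power beta = {network.beta}")

modules = ctnet.detect_module_set(network, X)
for lab in modules.module_labels():
    genes = set(modules.module_genes(lab))
    best = max(
        ((mid, len(genes & set(tg)) / len(genes | set(tg)))
         for mid, tg in truth.module_genes.items()),
        key=lambda x: x[1],
    )
    print(f"  module M{lab}: {len(genes)} genes; best ground-truth match "
          f"{best[0]} (Jaccard {best[1]:.2f})")
# Jaccard well above chance shows the branch cut recovered the planted
# modules; unassigned genes (label 0) are the background.
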