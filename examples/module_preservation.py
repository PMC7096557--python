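"""Permutation Zsummary: is a module found in one cell class's network
preserved in the other classes' networks?

Zsummary > 2 in every other class marks a shared (non-specific) module;
a median Zsummary < 2 across the other classes marks a module that
exists only in its own cell class.
"""

import numpy as np
import pandas as pd

import ctnet

dataset, truth = ctnet.generate_dataset(ctnet.default_config(seed=1))
pp = ctnet.correct_batch(ctnet.size_factor_normalize(ctnet.qc_filter(dataset)))
hvg = list(ctnet.select_hvgs(pp).selected_genes)
labels = pp.obs["cell_class"].to_numpy()
networks = {}
for cls in pd.unique(labels):
    cols = np.flatnonzero(labels == cls)
    networks[cls], _ = ctnet.build_network(
        pp.lognorm[np.ix_(pp.genes.get_indexer(hvg), cols)], pd.Index(hvg), cls
    )

for module_id, ref_class in [("planted_shared", "Gluta"), ("planted_ast", "Ast")]:
    genes = truth.module_genes[module_id]
    zs = {
        cls: ctnet.zsummary(networks[ref_class], networks[cls], genes,
                            n_perm=100, seed=7).zsummary
        for cls in networks if cls != ref_class
    }
    med = np.median(list(zs.values()))
    tag = "preserved everywhere" if med >= 2 else "cell type-specific"
    print(f"{module_id} (ref {ref_class}): median Zsummary = {med:6.2f}  -> {tag}")
    for cls, z in zs.items():
        print(f"    vs {cls:>6}: Zsummary {z:7.2f}")
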