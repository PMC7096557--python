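"""Generate the default synthetic snRNA-seq scenario and write it to disk.

The scenario plants three co-expression modules (one astrocyte-only
disease module, one module shared by every cell class, one
glutamatergic-only module), fold-8 marker panels per class, batch shifts
and a 150-gene disease list, so every downstream stage can be scored
against known ground truth.
"""

import ctnet

config = ctnet.default_config(seed=1)
dataset, truth = ctnet.generate_dataset(config)
paths = ctnet.write_dataset(dataset, truth, "scratch/example_dataset")

print(f"genes x nuclei : {dataset.n_genes} x {dataset.n_nuclei}")
print("nuclei per class:", dataset.obs["cell_class"].value_counts().to_dict())
print("planted modules :", {m: len(g) for m, g in truth.module_genes.items()})
print("disease genes   :", len(truth.disease_genes))
print("written to      :", paths["matrix"].parent)
# The class counts mirror a cortical dataset's skew (one dominant
# excitatory class); the module sizes are the planted ground truth that
# the network stage should rediscover.
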