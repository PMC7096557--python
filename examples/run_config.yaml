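# Full-pipeline configuration for the simulated example dataset.
#
# First generate the dataset, then run the workflow:
#
#   ctnet simulate --seed 1 --out scratch/example_dataset
#   ctnet run --config examples/run_config.yaml --out scratch/example_run
#
dataset_dir: scratch/example_dataset
disease_genes_path: scratch/example_dataset/disease_genes.txt
label_column: cell_class

# analysis thresholds (the defaults, spelled out)
alpha: 0.1
hvg_fdr: 0.1
min_module_size: 30
min_kme: 0.2
merge_cut_height: 0.2
top_n_specific: 500
top_n_hub: 50
zsummary_cutoff: 2.0
n_perm: 100
min_nuclei: 30

seed: 1
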