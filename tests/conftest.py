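import numpy as np
import pandas as pd
import pytest

import ctnet


@pytest.fixture(scope="session")
def default_run():
    """One default-scenario dataset taken through preprocessing and
    per-class network construction; shared by tests that only read it."""
    cfg = ctnet.default_config(seed=1)
    ds, gt = ctnet.generate_dataset(cfg)
    pp = ctnet.correct_batch(ctnet.size_factor_normalize(ctnet.qc_filter(ds)))
    hvg = ctnet.select_hvgs(pp)
    sel = list(hvg.selected_genes)
    labels = pp.obs["cell_class"].to_numpy()
    hvg_idx = pp.genes.get_indexer(sel)
    networks, class_X = {}, {}
    for cls in pd.unique(labels):
        cols = np.flatnonzero(labels == cls)
        net, Xn = ctnet.build_network(
            pp.lognorm[np.ix_(hvg_idx, cols)], pd.Index(sel), cls
        )
        networks[cls] = net
        class_X[cls] = Xn
    return {
        "config": cfg,
        "raw": ds,
        "truth": gt,
        "preprocessed": pp,
        "hvg": sel,
        "networks": networks,
        "class_X": class_X,
    }
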