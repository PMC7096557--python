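"""Shared constructions for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ctnet import PlantedModule, SynthConfig


def block_expression(
    block_sizes: list[int],
    within_r: float,
    n_noise: int,
    n_obs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian expression with planted correlated blocks.

    Each block shares one latent factor scaled so the typical within-block
    Pearson correlation is ``within_r``; per-gene loadings vary by +-40%
    so blocks have the hub-like connectivity heterogeneity real modules
    show. Noise genes are independent. Returns (matrix, true labels) with
    labels 1.. for blocks and 0 for noise.
    """
    lam = np.sqrt(within_r / (1.0 - within_r))
    rows, labels = [], []
    for b, s in enumerate(block_sizes, start=1):
        z = rng.standard_normal(n_obs)
        load = lam * rng.uniform(0.6, 1.4, size=s)
        rows.append(load[:, None] * z[None, :] + rng.standard_normal((s, n_obs)))
        labels.extend([b] * s)
    if n_noise:
        rows.append(rng.standard_normal((n_noise, n_obs)))
        labels.extend([0] * n_noise)
    return np.vstack(rows), np.array(labels)


def gene_index(n: int, prefix: str = "g") -> pd.Index:
    return pd.Index([f"{prefix}{i:04d}" for i in range(n)])


def small_scenario(seed: int = 0) -> SynthConfig:
    """A reduced planted scenario for fast pipeline-level tests.

    Same structure as the package default (one one-class disease module,
    one shared disease module, disjoint marker panels) at a fraction of
    the size.
    """
    n_genes = 600

    def gid(i: int) -> str:
        return f"G{i:04d}"

    classes = [("A", 150), ("B", 100), ("C", 60)]
    mod_a = tuple(gid(i) for i in range(0, 32))
    mod_shared = tuple(gid(i) for i in range(32, 64))
    modules = [
        PlantedModule("planted_a", mod_a, frozenset({"A"}), 0.8),
        PlantedModule("planted_shared", mod_shared, frozenset({"all"}), 0.8),
    ]
    markers = {}
    start = 100
    for lab, _ in classes:
        markers[lab] = {gid(i): 8.0 for i in range(start, start + 30)}
        start += 30
    markers["A"].update({g: 2.0 for g in mod_a})
    disease = set(mod_a[:16]) | set(mod_shared[:16]) | {gid(250 + 10 * k) for k in range(30)}
    return SynthConfig(
        n_genes=n_genes,
        cell_classes=classes,
        n_batches=2,
        batch_effect_sd=0.3,
        planted_modules=modules,
        disease_genes=frozenset(disease),
        marker_genes=markers,
        seed=seed,
    )
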