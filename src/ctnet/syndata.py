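"""Synthetic single-nucleus expression data with planted ground truth.

The generator emulates the structure of a cortical snRNA-seq experiment at
desk scale: a handful of cell classes with strongly unbalanced nucleus
counts, overdispersed (negative binomial) counts, gene-wise batch shifts,
cell-class marker genes with a known fold change, planted co-expression
modules driven by a shared latent factor (active either in one class or in
all classes), and a "disease" candidate gene list that overlaps chosen
modules. Every planted feature is recorded in a :class:`GroundTruth` object
so downstream stages can be scored against the truth.

Count model, per gene g and nucleus n of class c in batch b:

    counts[g, n] ~ NB(mean = mu[g, n], dispersion = d)        Var = m + d m^2
    log mu[g, n] = log(base_g) + log(fold_{g,c}) + delta_{g,b}
                   + sum_{modules M: g in M, c active} (l_g z_{M,n} - l_g^2 / 2)

with gene baselines base_g lognormal around ``baseline_mean``, marker folds
fold_{g,c} from the config, batch shifts delta_{g,b} ~ N(0, batch_effect_sd),
a standard normal latent z_{M,n} per module and nucleus, and per-gene
loadings l_g = latent_strength * u_g with u_g ~ U(0.5, 1.5) (hub-like
heterogeneity). The -l_g^2/2 term centres the latent so module membership
shapes the covariance, not the marginal mean.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ExpressionDataset, write_expression_dir

ALL_CLASSES = "all"

# Spread of the lognormal gene baseline means (natural-log sd).
_BASELINE_LOG_SD = 0.5
# Range of the per-gene latent loading multiplier.
_LOADING_RANGE = (0.5, 1.5)


class ConfigurationError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expressed gene module.

    ``active_in`` is a frozenset of cell class labels, or ``{"all"}`` for a
    module shared by every class. ``latent_strength`` in (0, 1) scales the
    shared latent factor and thereby the within-module Pearson correlation.
    """

    module_id: str
    genes: tuple[str, ...]
    active_in: frozenset[str]
    latent_strength: float

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ConfigurationError(f"module {self.module_id}: needs >= 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"module {self.module_id}: duplicate genes")
        if not self.active_in:
            raise ConfigurationError(f"module {self.module_id}: active_in is empty")
        if not 0 < self.latent_strength < 1:
            raise ConfigurationError(
                f"module {self.module_id}: latent_strength must be in (0, 1)"
            )


@dataclass
class SynthConfig:
    """Full description of a synthetic experiment."""

    n_genes: int
    cell_classes: list[tuple[str, int]]
    n_batches: int = 2
    batch_effect_sd: float = 0.3
    planted_modules: list[PlantedModule] = field(default_factory=list)
    disease_genes: frozenset[str] = frozenset()
    # cell class -> {gene -> fold_up}; fold applies in that class only
    marker_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_mean: float = 5.0
    dispersion: float = 0.3
    seed: int = 0

    def gene_ids(self) -> pd.Index:
        width = max(4, len(str(self.n_genes - 1)))
        return pd.Index([f"G{i:0{width}d}" for i in range(self.n_genes)])

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be positive")
        if self.batch_effect_sd < 0:
            raise ConfigurationError("batch_effect_sd must be non-negative")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be positive")
        if not self.cell_classes:
            raise ConfigurationError("at least one cell class required")
        labels = [lab for lab, _ in self.cell_classes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate cell class labels")
        for lab, n in self.cell_classes:
            if n < 1:
                raise ConfigurationError(f"cell class {lab!r} has {n} nuclei (needs >= 1)")
        universe = set(self.gene_ids())
        seen: set[str] = set()
        for mod in self.planted_modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ConfigurationError(
                    f"module {mod.module_id}: genes {sorted(overlap)[:5]} already "
                    "belong to another planted module"
                )
            seen |= set(mod.genes)
            missing = set(mod.genes) - universe
            if missing:
                raise ConfigurationError(
                    f"module {mod.module_id}: genes {sorted(missing)[:5]} outside the universe"
                )
            bad = mod.active_in - set(labels) - {ALL_CLASSES}
            if bad:
                raise ConfigurationError(
                    f"module {mod.module_id}: unknown cell classes in active_in: {sorted(bad)}"
                )
        bad_genes = set(self.disease_genes) - universe
        if bad_genes:
            raise ConfigurationError(
                f"disease genes outside the universe: {sorted(bad_genes)[:5]}"
            )
        for lab, folds in self.marker_genes.items():
            if lab not in labels:
                raise ConfigurationError(f"marker class {lab!r} not among cell classes")
            missing = set(folds) - universe
            if missing:
                raise ConfigurationError(
                    f"marker genes outside the universe for {lab!r}: {sorted(missing)[:5]}"
                )
            for g, f in folds.items():
                if f <= 1:
                    raise ConfigurationError(f"marker {g} in {lab!r}: fold_up must be > 1")

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | os.PathLike) -> None:
        payload = {
            "n_genes": self.n_genes,
            "cell_classes": [[lab, int(n)] for lab, n in self.cell_classes],
            "n_batches": self.n_batches,
            "batch_effect_sd": self.batch_effect_sd,
            "planted_modules": [
                {
                    "module_id": m.module_id,
                    "genes": list(m.genes),
                    "active_in": sorted(m.active_in),
                    "latent_strength": m.latent_strength,
                }
                for m in self.planted_modules
            ],
            "disease_genes": sorted(self.disease_genes),
            "marker_genes": {
                lab: {g: float(f) for g, f in sorted(folds.items())}
                for lab, folds in self.marker_genes.items()
            },
            "baseline_mean": self.baseline_mean,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SynthConfig":
        payload = yaml.safe_load(Path(path).read_text())
        modules = [
            PlantedModule(
                module_id=m["module_id"],
                genes=tuple(m["genes"]),
                active_in=frozenset(m["active_in"]),
                latent_strength=float(m["latent_strength"]),
            )
            for m in payload.get("planted_modules", [])
        ]
        return cls(
            n_genes=int(payload["n_genes"]),
            cell_classes=[(lab, int(n)) for lab, n in payload["cell_classes"]],
            n_batches=int(payload.get("n_batches", 2)),
            batch_effect_sd=float(payload.get("batch_effect_sd", 0.3)),
            planted_modules=modules,
            disease_genes=frozenset(payload.get("disease_genes", [])),
            marker_genes={
                lab: {g: float(f) for g, f in folds.items()}
                for lab, folds in payload.get("marker_genes", {}).items()
            },
            baseline_mean=float(payload.get("baseline_mean", 5.0)),
            dispersion=float(payload.get("dispersion", 0.3)),
            seed=int(payload.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset, serialisable to JSON."""

    module_genes: dict[str, list[str]]
    module_active_in: dict[str, list[str]]
    marker_genes: dict[str, dict[str, float]]
    disease_genes: list[str]
    batch_of_nucleus: dict[str, str]

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_dataset(config: SynthConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Sample a dataset with the planted structure described by ``config``.

    Deterministic: the same config (including seed) yields bit-identical
    counts, labels and ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}

    class_labels = np.concatenate(
        [np.repeat(lab, n) for lab, n in config.cell_classes]
    )
    n_nuclei = class_labels.size
    nucleus_ids = pd.Index([f"N{i:05d}" for i in range(n_nuclei)])

    # log-scale mean assembly (natural log)
    base = config.baseline_mean * np.exp(
        _BASELINE_LOG_SD * rng.standard_normal(config.n_genes)
        - 0.5 * _BASELINE_LOG_SD**2
    )
    logmu = np.tile(np.log(base)[:, None], (1, n_nuclei))

    for lab, folds in config.marker_genes.items():
        cols = np.flatnonzero(class_labels == lab)
        for g, f in folds.items():
            logmu[gene_pos[g], cols] += np.log(f)

    batch_idx = rng.integers(config.n_batches, size=n_nuclei)
    batch_labels = np.array([f"B{b}" for b in batch_idx])
    if config.n_batches > 1 or config.batch_effect_sd > 0:
        delta = rng.normal(0.0, config.batch_effect_sd, size=(config.n_genes, config.n_batches))
        logmu += delta[:, batch_idx]

    for mod in config.planted_modules:
        rows = np.array([gene_pos[g] for g in mod.genes])
        if ALL_CLASSES in mod.active_in:
            cols = np.arange(n_nuclei)
        else:
            cols = np.flatnonzero(np.isin(class_labels, list(mod.active_in)))
        loading = mod.latent_strength * rng.uniform(*_LOADING_RANGE, size=rows.size)
        z = rng.standard_normal(cols.size)
        logmu[np.ix_(rows, cols)] += loading[:, None] * z[None, :] - 0.5 * loading[:, None] ** 2

    mu = np.exp(logmu)
    d = config.dispersion
    counts = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * mu)).astype(np.int64)

    obs = pd.DataFrame(
        {
            "cell_class": class_labels,
            "cell_cluster": class_labels,  # one cluster per class at this scale
            "batch": batch_labels,
        },
        index=nucleus_ids,
    )
    dataset = ExpressionDataset(counts=counts, genes=genes, obs=obs)
    truth = GroundTruth(
        module_genes={m.module_id: list(m.genes) for m in config.planted_modules},
        module_active_in={m.module_id: sorted(m.active_in) for m in config.planted_modules},
        marker_genes={
            lab: {g: float(f) for g, f in folds.items()}
            for lab, folds in config.marker_genes.items()
        },
        disease_genes=sorted(config.disease_genes),
        batch_of_nucleus={nid: b for nid, b in zip(nucleus_ids, batch_labels)},
    )
    return dataset, truth


def write_dataset(
    dataset: ExpressionDataset,
    ground_truth: GroundTruth,
    directory: str | os.PathLike,
) -> dict[str, Path]:
    """Write dataset (MTX layout) and ground truth (JSON) under a directory."""
    if str(directory) == "":
        raise ValueError("empty directory path")
    paths = write_expression_dir(dataset, directory)
    gt_path = Path(directory) / "ground_truth.json"
    ground_truth.to_json(gt_path)
    paths["ground_truth"] = gt_path
    # the planted disease list doubles as a ready-made pipeline input
    disease_path = Path(directory) / "disease_genes.txt"
    disease_path.write_text("\n".join(sorted(ground_truth.disease_genes)) + "\n")
    paths["disease_genes"] = disease_path
    return paths


def default_config(seed: int = 0) -> SynthConfig:
    """The package's standard synthetic scenario.

    Five cell classes with a paper-like dominance skew, three planted
    modules (one astrocyte-only disease module, one module shared by all
    classes that also overlaps the disease list, one glutamatergic-only
    module without disease overlap), disjoint fold-8 marker panels per
    class, and a disease gene list of 150 genes.
    """
    n_genes = 3000
    width = max(4, len(str(n_genes - 1)))

    def gid(i: int) -> str:
        return f"G{i:0{width}d}"

    classes = [("Gluta", 600), ("GABA", 300), ("Ast", 150), ("Oligo", 100), ("OPC", 80)]
    mod_ast = tuple(gid(i) for i in range(0, 40))
    mod_shared = tuple(gid(i) for i in range(40, 80))
    mod_gluta = tuple(gid(i) for i in range(80, 130))
    modules = [
        PlantedModule("planted_ast", mod_ast, frozenset({"Ast"}), 0.8),
        PlantedModule("planted_shared", mod_shared, frozenset({ALL_CLASSES}), 0.8),
        PlantedModule("planted_gluta", mod_gluta, frozenset({"Gluta"}), 0.7),
    ]
    markers: dict[str, dict[str, float]] = {}
    start = 200
    for lab, _ in classes:
        markers[lab] = {gid(i): 8.0 for i in range(start, start + 60)}
        start += 60
    # one-class module genes are mildly elevated in their own class: cell
    # type-specific modules are made of genes expressed in that cell type
    markers["Ast"].update({g: 2.0 for g in mod_ast})
    markers["Gluta"].update({g: 2.0 for g in mod_gluta})

    disease = set(mod_ast[:20]) | set(mod_shared[:20])
    disease |= {gid(500 + 20 * k) for k in range(110)}

    return SynthConfig(
        n_genes=n_genes,
        cell_classes=classes,
        n_batches=2,
        batch_effect_sd=0.3,
        planted_modules=modules,
        disease_genes=frozenset(disease),
        marker_genes=markers,
        baseline_mean=5.0,
        dispersion=0.3,
        seed=seed,
    )
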