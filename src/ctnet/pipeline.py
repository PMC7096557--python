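"""End-to-end orchestration: preprocess -> specificity -> per-class
networks -> cross-class preservation -> enrichment -> module selection.

For every cell class with enough nuclei a weighted co-expression network
is built on the highly-variable-gene universe and its modules detected.
Each module is then screened by three enrichment filters (disease genes,
own-class marker panel, absence of other-class marker panels) and by the
median preservation Zsummary across the other classes' networks; modules
passing everything are reported as cell class-specific disease-associated
modules, with a Cytoscape-ready hub-gene export.

All outputs are plain TSV/CSV written under ``out_dir``; a rerun with the
same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import ExpressionDataset, read_expression_dir
from .preprocess import qc_filter, size_factor_normalize, cpm, correct_batch, select_hvgs
from .specificity import compute_specificity, top_specific_genes
from .coexpression import build_network, detect_module_set, export_top_hub_network
from .preservation import preservation_report, summarize_preservation
from .enrichment import enrichment_matrix, annotate_modules_gmt, select_modules, read_gmt

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "specificity", "network", "preserve", "enrich", "export")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    dataset_dir: str | None = None
    disease_genes_path: str | None = None
    gmt_path: str | None = None
    out_dir: str | None = None
    label_column: str = "cell_class"
    exclude_labels: list[str] = field(default_factory=list)
    exclude_genes: list[str] = field(default_factory=list)
    # thresholds
    alpha: float = 0.1
    hvg_fdr: float = 0.1
    n_mads: float = 3.0
    min_module_size: int = 30
    deep_split: int = 2
    min_kme: float = 0.2
    merge_cut_height: float = 0.2
    top_n_specific: int = 500
    top_n_hub: int = 50
    zsummary_cutoff: float = 2.0
    n_perm: int = 100
    min_nuclei: int = 30
    pseudocount: float = 1.0
    specificity_genes: str = "all"  # "all" or "hvg"
    gmt_min_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "alpha", "hvg_fdr", "n_mads", "min_module_size", "min_kme",
            "merge_cut_height", "top_n_specific", "top_n_hub", "zsummary_cutoff",
            "n_perm", "min_nuclei",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.specificity_genes not in ("all", "hvg"):
            raise ValueError("specificity_genes must be 'all' or 'hvg'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output destination excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, with full provenance."""

    config: RunConfig
    class_summary: pd.DataFrame
    skipped_classes: dict[str, str]
    hvg_genes: list[str]
    specificity: object | None
    module_sets: dict
    networks: dict
    enrichment: pd.DataFrame | None
    gmt_annotation: pd.DataFrame | None
    preservation: pd.DataFrame | None
    preservation_summary: pd.DataFrame | None
    verdicts: pd.DataFrame | None
    final_modules: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _read_gene_list(path: str | Path) -> list[str]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"gene list not found: {p}")
    return [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(
    config: RunConfig,
    dataset: ExpressionDataset | None = None,
    disease_genes: list[str] | None = None,
    stop_after: str | None = None,
) -> RunReport:
    """Execute the workflow; ``stop_after`` truncates at a named stage.

    ``dataset`` and ``disease_genes`` may be passed directly (library use)
    or read from the paths in the config (CLI use).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def done(stage: str) -> bool:
        return stop_after == stage

    report = RunReport(
        config=config, class_summary=pd.DataFrame(), skipped_classes={},
        hvg_genes=[], specificity=None, module_sets={}, networks={},
        enrichment=None, gmt_annotation=None, preservation=None,
        preservation_summary=None, verdicts=None, final_modules=[], paths=paths,
    )

    # ---- stage: preprocess -------------------------------------------------
    stage = "preprocess"
    try:
        if dataset is None:
            if not config.dataset_dir:
                raise FileNotFoundError("no dataset given and no dataset_dir configured")
            dataset = read_expression_dir(config.dataset_dir)
        ds = qc_filter(dataset, n_mads=config.n_mads, exclude_genes=config.exclude_genes)
        ds = size_factor_normalize(ds)
        if "batch" in ds.obs.columns and ds.obs["batch"].nunique() > 1:
            ds = correct_batch(ds, "batch")
        hvg = select_hvgs(ds, fdr=config.hvg_fdr)
        hvg_genes = list(hvg.selected_genes)
        report.hvg_genes = hvg_genes
        if out:
            paths["hvg"] = out / "preprocess" / "hvg.tsv"
            paths["hvg"].parent.mkdir(parents=True, exist_ok=True)
            hvg.to_tsv(paths["hvg"])
            hvg_idx = ds.genes.get_indexer(hvg_genes)
            lognorm = pd.DataFrame(ds.lognorm[hvg_idx], index=pd.Index(hvg_genes, name="gene"),
                                   columns=ds.nuclei)
            paths["lognorm"] = out / "preprocess" / "lognorm_hvg.csv"
            lognorm.to_csv(paths["lognorm"], float_format=_FLOAT_FMT)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if done(stage):
        return report

    # ---- stage: specificity ------------------------------------------------
    stage = "specificity"
    try:
        labels = ds.obs[config.label_column].to_numpy()
        cpm_matrix = cpm(ds)
        if config.specificity_genes == "hvg":
            gene_mask = ds.genes.isin(hvg_genes)
            spec_genes = ds.genes[gene_mask]
            spec_cpm = cpm_matrix[gene_mask]
        else:
            spec_genes, spec_cpm = ds.genes, cpm_matrix
        spec = compute_specificity(
            spec_cpm, spec_genes, labels,
            pseudocount=config.pseudocount,
            exclude_labels=tuple(config.exclude_labels),
        )
        report.specificity = spec
        panels = {
            t: top_specific_genes(spec, t, n=config.top_n_specific)
            for t in spec.cell_types
        }
        if out:
            paths["specificity"] = out / "specificity" / "specificity.tsv"
            paths["specificity"].parent.mkdir(parents=True, exist_ok=True)
            spec.to_tsv(paths["specificity"])
            for t, panel in panels.items():
                p = out / "specificity" / "panels" / f"{t}.txt"
                p.parent.mkdir(parents=True, exist_ok=True)
                panel.write(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if done(stage):
        return report

    # ---- stage: network ----------------------------------------------------
    stage = "network"
    try:
        hvg_idx = ds.genes.get_indexer(hvg_genes)
        class_rows = []
        networks, module_sets, class_X = {}, {}, {}
        analyzed_labels = [t for t in pd.unique(labels) if t not in config.exclude_labels]
        for t in analyzed_labels:
            cols = np.flatnonzero(labels == t)
            if len(cols) < config.min_nuclei:
                report.skipped_classes[t] = (
                    f"only {len(cols)} nuclei (< min_nuclei {config.min_nuclei})"
                )
                logger.info("skipping class %s: %s", t, report.skipped_classes[t])
                continue
            X = ds.lognorm[np.ix_(hvg_idx, cols)]
            net, Xn = build_network(X, pd.Index(hvg_genes), cell_type=t)
            mods = detect_module_set(
                net, Xn,
                min_module_size=config.min_module_size,
                deep_split=config.deep_split,
                merge_cut_height=config.merge_cut_height,
                min_kme=config.min_kme,
            )
            networks[t] = net
            class_X[t] = Xn
            sizes = {lab: len(mods.module_genes(lab)) for lab in mods.module_labels()}
            for lab in mods.module_labels():
                module_sets[f"{t}_M{lab}"] = (t, mods.module_genes(lab))
            class_rows.append(
                {
                    "cell_class": t,
                    "n_nuclei": len(cols),
                    "n_genes": len(net.genes),
                    "beta": net.beta,
                    "n_modules": len(sizes),
                    "module_sizes": ",".join(str(sizes[k]) for k in sorted(sizes)),
                }
            )
            if out:
                d = out / "networks" / t
                _write_tsv(mods.assignment_frame(), d / "modules.tsv")
                mods.eigengenes.set_axis(ds.nuclei[cols], axis=0).to_csv(
                    d / "eigengenes.csv", float_format=_FLOAT_FMT
                )
            report.module_sets[t] = mods
        report.networks = networks
        report.class_summary = pd.DataFrame(class_rows)
        if len(networks) < 2:
            raise ValueError(
                f"only {len(networks)} cell classes met the min-nuclei bar; >= 2 required"
            )
        if out:
            _write_tsv(report.class_summary, out / "networks" / "summary.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if done(stage):
        return report

    # ---- stage: preserve ---------------------------------------------------
    stage = "preserve"
    try:
        pres_seed = (config.seed * 9973 + 17) % (2**31 - 1)
        pres = preservation_report(
            networks, module_sets, n_perm=config.n_perm, seed=pres_seed
        )
        pres_summary = summarize_preservation(pres, config.zsummary_cutoff)
        report.preservation = pres
        report.preservation_summary = pres_summary
        if out:
            _write_tsv(pres, out / "preservation" / "preservation.tsv")
            _write_tsv(pres_summary, out / "preservation" / "summary.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if done(stage):
        return report

    # ---- stage: enrich -----------------------------------------------------
    stage = "enrich"
    try:
        if disease_genes is None:
            if not config.disease_genes_path:
                raise FileNotFoundError(
                    "no disease gene list given and no disease_genes_path configured"
                )
            disease_genes = _read_gene_list(config.disease_genes_path)
        universe = hvg_genes
        modules_flat = {name: genes for name, (cls, genes) in module_sets.items()}
        gene_sets: dict[str, set] = {"disease": set(disease_genes)}
        marker_set_of_class = {}
        for t, panel in panels.items():
            name = f"markers_{t}"
            gene_sets[name] = set(panel.genes)
            marker_set_of_class[t] = name
        enr = enrichment_matrix(modules_flat, gene_sets, universe, alpha=config.alpha)
        report.enrichment = enr
        median_z = dict(
            zip(pres_summary["module"], pres_summary["median_zsummary"])
        )
        module_class = {name: cls for name, (cls, _) in module_sets.items()}
        # marker panels only exist for analyzed classes; a module can only
        # come from an analyzed class, so the mapping is complete
        marker_map = {c: marker_set_of_class[c] for c in networks}
        verdicts = select_modules(
            enr, module_class, "disease", marker_map, median_z,
            alpha=config.alpha, zsummary_cutoff=config.zsummary_cutoff,
        )
        report.verdicts = verdicts
        report.final_modules = sorted(verdicts.loc[verdicts["final_specific"], "module"])
        if config.gmt_path:
            gmt = read_gmt(config.gmt_path)
            report.gmt_annotation = annotate_modules_gmt(
                modules_flat, gmt, universe,
                alpha=config.alpha, min_genes=config.gmt_min_genes,
            )
        if out:
            _write_tsv(enr, out / "enrichment" / "enrichment_long.tsv")
            _write_tsv(verdicts, out / "enrichment" / "verdicts.tsv")
            heat = enr.pivot_table(index="module", columns="gene_set", values="q")
            heat = -np.log10(heat.clip(lower=1e-300))
            _write_tsv(heat.sort_index(), out / "enrichment" / "neglog10_q_matrix.tsv", index=True)
            if report.gmt_annotation is not None:
                _write_tsv(report.gmt_annotation, out / "enrichment" / "gmt_annotation.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    if done(stage):
        return report

    # ---- stage: export -----------------------------------------------------
    stage = "export"
    try:
        disease_set = set(disease_genes)
        for name in report.final_modules:
            cls, _genes = module_sets[name]
            lab = int(name.rsplit("_M", 1)[1])
            mods = report.module_sets[cls]
            nodes, edges = export_top_hub_network(
                mods, networks[cls].tom, lab, n=config.top_n_hub,
                disease_genes=disease_set,
            )
            if out:
                d = out / "hub_networks"
                _write_tsv(nodes, d / f"{name}_nodes.tsv")
                _write_tsv(edges, d / f"{name}_edges.tsv")
        if out:
            summary = {
                "package_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_hvg": len(hvg_genes),
                "analyzed_classes": sorted(networks),
                "skipped_classes": report.skipped_classes,
                "n_modules": len(module_sets),
                "final_specific_modules": report.final_modules,
            }
            (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return report
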