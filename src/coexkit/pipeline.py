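"""End-to-end orchestration: counts -> modules -> enrichment -> bottlenecks.

``run_all`` executes the stages in analysis order — replicate combination,
TPM, log transform, expression and variance filters, soft-threshold pick,
network fit, module-trait statistics, tissue-specificity scan, per-module
randomization tests, gene-set enrichment, and PPI bottleneck calling —
persisting every intermediate as TSV/JSON under an output directory and
returning a manifest of SHA-256 checksums.  The single mandatory seed is
expanded into independent per-stage streams with a counter scheme
(``SeedSequence([seed, stage_index])``), so adding a stage never perturbs
the draws of earlier ones.  Identical config + seed give byte-identical
outputs and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import CoexpressionNetwork, NetworkConfig
from .enrichment import (
    enrichment_table,
    gene_set_enrichment,
    randomization_module_test,
    tissue_specificity_scan,
    upregulated_sets,
)
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    PPIEdgeList,
    TraitDesign,
    combine_technical_replicates,
    read_de_table,
    read_expression_matrix,
    read_gene_annotation,
    read_gmt,
    read_ppi_edges,
    read_traits,
    write_de_table,
    write_expression_matrix,
    write_gene_annotation,
    write_gmt,
    write_ppi_edges,
    write_traits,
)
from .normalization import (
    compute_tpm,
    filter_expressed,
    log_transform,
    select_top_expressed,
    select_top_quartile_variance,
)
from .ppi import bottleneck_analysis
from .simulate import (
    SimulationConfig,
    de_table_from_truth,
    gene_sets_from_truth,
    simulate_expression,
    simulate_ppi,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Everything a full run needs: inputs (files or simulation), parameters, seed."""

    seed: int
    out_dir: str = "coexkit_run"
    # either a simulation config ...
    simulate: Optional[SimulationConfig] = None
    # ... or paths to real inputs
    counts_path: Optional[str] = None
    annotation_path: Optional[str] = None
    traits_path: Optional[str] = None
    de_table_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    ppi_edges_path: Optional[str] = None
    ppi_score_scale: str = "unit"
    replicate_groups: dict = field(default_factory=dict)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    expressed_tpm_threshold: float = 1.0
    fc_threshold: float = 2.0
    padj_threshold: float = 0.01
    enrich_min_genes: int = 5
    enrich_fdr_max: float = 0.05
    enrich_fold_min: float = 1.5
    n_random: int = 10000
    top_expressed_cell_type: Optional[str] = None
    top_expressed_n: int = 1000
    ppi_weight_min: float = 0.7
    bottleneck_percentile: float = 95.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = SimulationConfig(**sim)
        if "network" in raw and raw["network"] is not None:
            raw["network"] = NetworkConfig(**raw["network"])
        return cls(**raw)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.ndarray, tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj
        return convert(self)


@dataclass
class RunManifest:
    """Deterministic record of a run: config hash, per-stage output checksums."""

    config_hash: str
    seed: int
    stages: dict  # stage name -> {relative path -> sha256}
    versions: dict
    warnings: list

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; see the module docstring for the stage order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, str]] = {}
    warnings_log: list[str] = []

    def record(stage: str, *paths: Path) -> None:
        stages.setdefault(stage, {})
        for p in paths:
            stages[stage][p.name] = _sha256(p)
        logger.info("[stage:%s] wrote %s", stage, ", ".join(p.name for p in paths))

    def guard(stage: str):
        class _Guard:
            def __enter__(self):
                logger.info("[stage:%s] start", stage)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        return _Guard()

    truth = None
    with guard("inputs"):
        if config.simulate is not None:
            counts, annotation, traits, truth = simulate_expression(config.simulate)
            edges, truth = simulate_ppi(truth, seed=_stage_seed(config.seed, 1))
            de = de_table_from_truth(truth)
            collection = gene_sets_from_truth(truth, seed=_stage_seed(config.seed, 2))
            write_expression_matrix(counts, out / "counts.tsv")
            write_gene_annotation(annotation, out / "annotation.tsv")
            write_traits(traits, out / "traits.tsv")
            write_ppi_edges(edges, out / "ppi_edges.tsv")
            write_de_table(de, out / "de_table.tsv")
            write_gmt(collection, out / "gene_sets.gmt")
            truth.to_json(out / "truth.json")
            record("inputs", out / "counts.tsv", out / "annotation.tsv",
                   out / "traits.tsv", out / "ppi_edges.tsv", out / "de_table.tsv",
                   out / "gene_sets.gmt", out / "truth.json")
        else:
            if not (config.counts_path and config.annotation_path and config.traits_path):
                raise ValueError("counts_path, annotation_path and traits_path are required "
                                 "when no simulation is configured")
            counts = read_expression_matrix(config.counts_path, "raw_counts")
            annotation = read_gene_annotation(config.annotation_path)
            traits = read_traits(config.traits_path)
            de = read_de_table(config.de_table_path) if config.de_table_path else None
            collection = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
            edges = (read_ppi_edges(config.ppi_edges_path, config.ppi_score_scale)
                     if config.ppi_edges_path else None)

    with guard("combine_replicates"):
        if config.replicate_groups:
            counts = combine_technical_replicates(counts, config.replicate_groups)
            write_expression_matrix(counts, out / "counts_combined.tsv")
            record("combine_replicates", out / "counts_combined.tsv")

    with guard("normalize"):
        tpm = compute_tpm(counts, annotation)
        logtpm = log_transform(tpm)
        write_expression_matrix(tpm, out / "tpm.tsv")
        write_expression_matrix(logtpm, out / "logtpm.tsv")
        record("normalize", out / "tpm.tsv", out / "logtpm.tsv")

    with guard("select"):
        expressed = filter_expressed(tpm, config.expressed_tpm_threshold)
        quartile = select_top_quartile_variance(logtpm, expressed.selected_gene_ids)
        sel = pd.DataFrame({
            "gene_id": list(expressed.selected_gene_ids),
            "criterion": ["tpm_gt1"] * len(expressed),
        })
        sel.loc[sel["gene_id"].isin(quartile.selected_gene_ids), "criterion"] = \
            "top_quartile_variance"
        sel.to_csv(out / "selection.tsv", sep="\t", index=False)
        record("select", out / "selection.tsv")

    with guard("network"):
        net_expr = logtpm.values.loc[list(quartile.selected_gene_ids)]
        model = CoexpressionNetwork(net_expr, traits, config.network)
        results = model.fit()
        results.labels.rename("module").to_csv(out / "module_labels.tsv", sep="\t",
                                               index_label="gene_id")
        results.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
        results.kme.to_csv(out / "kme.tsv", sep="\t", index_label="gene_id",
                           float_format="%.6g")
        results.fit_table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        if results.trait_correlation is not None:
            results.trait_correlation.to_csv(out / "module_trait_r.tsv", sep="\t",
                                             index_label="module", float_format="%.6g")
            results.trait_p.to_csv(out / "module_trait_p.tsv", sep="\t",
                                   index_label="module", float_format="%.6g")
            record("network", out / "module_labels.tsv", out / "eigengenes.tsv",
                   out / "kme.tsv", out / "soft_threshold.tsv",
                   out / "module_trait_r.tsv", out / "module_trait_p.tsv")
        else:
            record("network", out / "module_labels.tsv", out / "eigengenes.tsv",
                   out / "kme.tsv", out / "soft_threshold.tsv")
        if not results.reached_target:
            warnings_log.append("scale-free fit target not reached")

    with guard("tissue_scan"):
        cell_type = config.top_expressed_cell_type or traits.cell_types[0]
        n_top = min(config.top_expressed_n, logtpm.n_genes)
        top = select_top_expressed(logtpm, traits, cell_type, n_top)
        scan = tissue_specificity_scan(top.selected_gene_ids, annotation)
        enrichment_table(scan).to_csv(out / "tissue_enrichment.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        record("tissue_scan", out / "tissue_enrichment.tsv")

    with guard("randomization"):
        if de is not None:
            up_a, up_b = upregulated_sets(de, config.fc_threshold, config.padj_threshold)
            universe = list(quartile.selected_gene_ids)
            target = set(up_a) & set(universe)
            rows = []
            for i, m in enumerate(results.modules):
                res = randomization_module_test(
                    results.module_genes(m), target, universe,
                    n_random=config.n_random,
                    seed=_stage_seed(config.seed, 100 + i),
                    module_name=f"M{m}",
                )
                rows.append({
                    "module": res.module_name, "observed": res.observed,
                    "n_random": res.n_random, "null_mean": res.null_mean,
                    "null_sd": res.null_sd, "null_max": res.null_max,
                    "p_value": res.p_value, "p_display": res.formatted_p(),
                    "seed": res.seed,
                })
            pd.DataFrame(rows).to_csv(out / "randomization.tsv", sep="\t", index=False,
                                      float_format="%.6g")
            record("randomization", out / "randomization.tsv")

    with guard("gene_set_enrichment"):
        if collection is not None:
            frames = []
            for m in results.modules:
                query = [g for g in results.module_genes(m) if g in collection.universe]
                if not query:
                    continue
                res = gene_set_enrichment(query, collection, config.enrich_min_genes,
                                          config.enrich_fdr_max, config.enrich_fold_min)
                frame = enrichment_table(res)
                frame.insert(0, "module", f"M{m}")
                frames.append(frame)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "module_enrichment.tsv", sep="\t", index=False,
                    float_format="%.6g")
                record("gene_set_enrichment", out / "module_enrichment.tsv")

    with guard("ppi"):
        if edges is not None:
            module_genes: set[str] = set()
            for m in results.modules:
                module_genes |= set(results.module_genes(m))
            edge_nodes = set(edges.edges["protein_a"]) | set(edges.edges["protein_b"])
            ppi_genes = module_genes | edge_nodes
            ppi = bottleneck_analysis(edges, ppi_genes, config.ppi_weight_min,
                                      config.bottleneck_percentile)
            rows = [{"gene_id": g, "betweenness": ppi.betweenness[g],
                     "is_bottleneck": g in ppi.bottlenecks}
                    for g in sorted(ppi.betweenness)]
            pd.DataFrame(rows).to_csv(out / "bottlenecks.tsv", sep="\t", index=False,
                                      float_format="%.10g")
            sub = pd.DataFrame(sorted(tuple(sorted(e)) for e in ppi.graph.edges),
                               columns=["protein_a", "protein_b"])
            sub.to_csv(out / "ppi_subgraph.tsv", sep="\t", index=False)
            record("ppi", out / "bottlenecks.tsv", out / "ppi_subgraph.tsv")

    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    config_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=config.seed,
        stages=stages,
        versions={
            "coexkit": __version__,
            "python": ".".join(map(str, sys.version_info[:3])),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        warnings=warnings_log,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
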