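"""End-to-end orchestration: data → DE → STC → enrichment → network.

A single :class:`PipelineConfig` carries every stage threshold (defaults
follow the conventional reporting thresholds for this kind of analysis:
DE at p < 0.01 with 5% FDR, pathway enrichment at Fisher p < 0.001) and a
single global seed from which per-stage seeds are derived by fixed offsets
(synthesis +0, annotations +1, STC permutations +2, GA +3), so one knob
controls reproducibility while the stages draw from independent streams.

Every stage writes its table before the next starts, so a failing stage
leaves completed intermediates on disk; a manifest (JSON) records the full
normalised configuration, and re-running from the manifest reproduces all
outputs (bitwise for deterministic stages, seed-identical for the GA and
permutation stages).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as dio
from .ctrnn import CTRNN, GAConfig, rank_regulators, decompose_subnetworks
from .datatypes import ExpressionMatrix, GeneSetCollection, InteractionCatalog
from .enrichment import enrich
from .rvm import estimate_rvm_hyperparams, residual_variances, rvm_f_test, select_degs
from .stc import (
    anchored_mean_profiles,
    assign_genes_to_profiles,
    build_profile_templates,
    profile_significance,
    significant_templates,
)
from .synth import (
    DEFAULT_REPLICATES,
    DEFAULT_TIMEPOINTS,
    generate_annotations,
    generate_ground_truth_network,
    simulate_dataset,
)

_SEED_MOD = 2**31


@dataclass
class SynthConfig:
    n_genes: int = 50
    density: float = 0.04
    n_hubs: int = 2
    weight_scale: float = 1.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = DEFAULT_REPLICATES
    noise_sd: float = 0.1
    n_null_genes: int = 150
    n_categories: int = 30
    enriched_categories: int = 5
    category_size: int = 15
    dropout: float = 0.3


@dataclass
class PipelineConfig:
    # inputs: either file paths or synthetic generation
    expression: str | None = None
    design: str | None = None
    gmt: str | None = None
    catalog: str | None = None
    synth: SynthConfig | None = None
    # differential expression
    de_p_threshold: float = 0.01
    de_q_threshold: float = 0.05
    # temporal clustering
    stc_max_unit_change: int = 1
    stc_permutations: int = 300
    stc_p_threshold: float = 0.05
    top_k_profiles: int | None = None
    # enrichment
    enrich_mode: str = "kegg"  # "kegg" (p<0.001) or "go" (p<0.05)
    enrich_p_threshold: float | None = None
    min_category_size: int = 3
    # network: consensus of several moderate GA runs ranks regulators more
    # stably than one long run (run-idiosyncratic weights average away)
    ga: GAConfig = field(
        default_factory=lambda: GAConfig(
            population_size=160,
            generations=300,
            mutation_rate=0.02,
            sparsity_lambda=0.005,
            prune_eps=0.05,
            n_runs=4,
        )
    )
    rel_threshold: float = 0.10
    node_set: str = "pathway"  # "pathway": DE genes in significant categories; "all_de"
    restrict_to_catalog: bool = False
    # global
    seed: int = 0
    outdir: str = "dyngrn_run"

    def __post_init__(self) -> None:
        if self.enrich_p_threshold is None:
            self.enrich_p_threshold = 0.001 if self.enrich_mode == "kegg" else 0.05


def validate_config(raw: dict[str, Any]) -> PipelineConfig:
    """Normalise a raw config mapping; unknown keys are rejected."""
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
    if "synth" in raw and raw["synth"] is not None and not isinstance(raw["synth"], SynthConfig):
        synth_raw = dict(raw["synth"])
        synth_known = {f.name for f in dataclasses.fields(SynthConfig)}
        unknown = set(synth_raw) - synth_known
        if unknown:
            raise ValueError(f"unknown synth config key {sorted(unknown)[0]!r}")
        if "timepoints" in synth_raw:
            synth_raw["timepoints"] = tuple(float(t) for t in synth_raw["timepoints"])
        raw["synth"] = SynthConfig(**synth_raw)
    if "ga" in raw and raw["ga"] is not None and not isinstance(raw["ga"], GAConfig):
        ga_raw = dict(raw["ga"])
        ga_known = {f.name for f in dataclasses.fields(GAConfig)}
        unknown = set(ga_raw) - ga_known
        if unknown:
            raise ValueError(f"unknown GA config key {sorted(unknown)[0]!r}")
        for key in ("weight_bounds", "tau_bounds", "theta_bounds"):
            if key in ga_raw:
                ga_raw[key] = tuple(float(x) for x in ga_raw[key])
        raw["ga"] = GAConfig(**ga_raw)
    config = PipelineConfig(**raw)
    if config.stc_permutations < 0:
        raise ValueError("stc_permutations must be non-negative")
    if config.enrich_mode not in ("kegg", "go"):
        raise ValueError(f"unknown enrich_mode {config.enrich_mode!r}")
    if config.node_set not in ("pathway", "all_de"):
        raise ValueError(f"unknown node_set {config.node_set!r}")
    if config.synth is None:
        if config.expression is None or config.design is None:
            raise ValueError("either file inputs or a synth block is required")
        if config.restrict_to_catalog and config.catalog is None:
            raise ValueError("restrict_to_catalog requires an interaction catalog")
    return config


def _config_to_jsonable(config: PipelineConfig) -> dict[str, Any]:
    d = asdict(config)
    if d.get("synth") is not None:
        d["synth"]["timepoints"] = list(d["synth"]["timepoints"])
    for key in ("weight_bounds", "tau_bounds", "theta_bounds"):
        d["ga"][key] = list(d["ga"][key])
    return d


def _stage_seed(config: PipelineConfig, offset: int) -> int:
    return (config.seed + offset) % _SEED_MOD


class StageError(RuntimeError):
    """A pipeline stage failed; completed intermediates remain on disk."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synth is not None:
        s = config.synth
        truth = generate_ground_truth_network(
            s.n_genes, s.density, s.n_hubs, s.weight_scale, seed=_stage_seed(config, 0)
        )
        dataset = simulate_dataset(
            truth,
            timepoints=s.timepoints,
            replicates=s.replicates,
            noise_sd=s.noise_sd,
            n_null_genes=s.n_null_genes,
            seed=_stage_seed(config, 0),
        )
        sets, catalog = generate_annotations(
            dataset,
            n_categories=s.n_categories,
            enriched_categories=s.enriched_categories,
            dropout=s.dropout,
            category_size=s.category_size,
            seed=_stage_seed(config, 1),
        )
        dio.write_expression_tsv(
            dataset.expression, outdir / "expression.tsv", outdir / "design.tsv"
        )
        dio.write_gmt(sets, outdir / "gene_sets.gmt")
        dio.write_interaction_table(catalog, outdir / "catalog.tsv")
        truth_edges = pd.DataFrame(
            truth.true_edges(), columns=["source", "target", "weight"]
        )
        truth_edges.to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)
        with open(outdir / "truth_hubs.txt", "w") as fh:
            fh.write("\n".join(truth.hub_ids) + "\n")
        return dataset.expression, sets, catalog, dataset
    matrix = dio.read_expression_tsv(config.expression, config.design)
    sets = dio.read_gmt(config.gmt) if config.gmt else None
    catalog = dio.read_interaction_table(config.catalog) if config.catalog else None
    return matrix, sets, catalog, None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute DE → STC → enrichment → network and write all outputs.

    Returns the run report (also written to ``report.json``); the full
    normalised configuration goes to ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_config_to_jsonable(config), fh, indent=2)
    report: dict[str, Any] = {"outdir": str(outdir), "seed": config.seed}

    # --- inputs ---------------------------------------------------------------
    try:
        matrix, sets, catalog, dataset = _load_inputs(config, outdir)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc) from exc
    report["n_genes"] = matrix.n_genes
    report["n_samples"] = len(matrix.sample_ids)
    report["n_timepoints"] = len(matrix.timepoints)

    # --- differential expression ---------------------------------------------
    try:
        variances, d2 = residual_variances(matrix)
        params = estimate_rvm_hyperparams(variances, d2)
        de = rvm_f_test(matrix, params)
        de = select_degs(de, config.de_p_threshold, config.de_q_threshold)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("differential_expression", exc) from exc
    de_genes = list(de.loc[de["selected"], "gene_id"])
    report["rvm_a"] = params.a
    report["rvm_b"] = params.b
    report["n_de_genes"] = len(de_genes)

    # --- temporal clustering --------------------------------------------------
    try:
        templates = build_profile_templates(
            len(matrix.timepoints), config.stc_max_unit_change
        )
        if de_genes:
            profiles = anchored_mean_profiles(matrix, de_genes)
            assigned = assign_genes_to_profiles(profiles, templates)
            assigned = profile_significance(
                assigned, config.stc_permutations, seed=_stage_seed(config, 2)
            )
            assigned.stats.to_csv(outdir / "stc_templates.tsv", sep="\t", index=False)
            assigned.assignments.to_csv(
                outdir / "stc_assignments.tsv", sep="\t", index=False
            )
            sig_templates = significant_templates(
                assigned, config.stc_p_threshold, config.top_k_profiles
            )
        else:
            pd.DataFrame(
                columns=["template_id", "transitions", "observed", "expected", "p_value"]
            ).to_csv(outdir / "stc_templates.tsv", sep="\t", index=False)
            pd.DataFrame(columns=["gene_id", "template_id", "correlation"]).to_csv(
                outdir / "stc_assignments.tsv", sep="\t", index=False
            )
            sig_templates = pd.DataFrame(columns=["template_id", "p_value"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("stc", exc) from exc
    report["n_templates"] = templates.n_templates
    report["n_significant_templates"] = len(sig_templates)

    # --- enrichment -----------------------------------------------------------
    enriched = pd.DataFrame()
    try:
        if sets is not None:
            enriched = enrich(
                set(de_genes),
                set(matrix.gene_ids),
                sets,
                p_threshold=config.enrich_p_threshold,
                min_category_size=config.min_category_size,
            )
            enriched.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", exc) from exc
    flagged = (
        list(enriched.loc[enriched["significant"], "category"])
        if len(enriched)
        else []
    )
    report["n_categories_tested"] = len(enriched)
    report["n_categories_significant"] = len(flagged)

    # --- network --------------------------------------------------------------
    try:
        if config.node_set == "pathway" and sets is not None and flagged:
            pathway_genes = set().union(*(sets[c] for c in flagged))
            nodes = [g for g in de_genes if g in pathway_genes]
        else:
            nodes = list(de_genes)
        report["n_network_genes"] = len(nodes)
        if len(nodes) >= 2:
            ga = dataclasses.replace(
                config.ga,
                seed=_stage_seed(config, 3),
                restrict_to_catalog=config.restrict_to_catalog,
            )
            model = CTRNN.from_expression(matrix, genes=nodes, catalog=catalog)
            results = model.fit(ga)
            edges = results.extract_edges(config.rel_threshold)
            regulators = rank_regulators(edges)
            subnets = decompose_subnetworks(edges)
            dio.write_network(edges, outdir / "edges.tsv", "edge-table")
            dio.write_network(edges, outdir / "edges.sif", "sif")
            dio.write_network(edges, outdir / "edges.graphml", "graphml")
            regulators.to_csv(outdir / "regulators.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "generation": results.fitness_trace.generation,
                    "best_fitness": results.fitness_trace.best_fitness,
                }
            ).to_csv(outdir / "fitness_trace.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    (i, ";".join(sorted(sn.nodes)), len(sn.nodes), len(sn.edges))
                    for i, sn in enumerate(subnets)
                ],
                columns=["subnetwork", "nodes", "n_nodes", "n_edges"],
            ).to_csv(outdir / "subnetworks.tsv", sep="\t", index=False)
            with open(outdir / "network_summary.txt", "w") as fh:
                fh.write(results.summary(config.rel_threshold) + "\n")
        else:
            edges, regulators, subnets, results = [], pd.DataFrame(), [], None
            dio.write_network([], outdir / "edges.tsv", "edge-table")
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    by_prov: dict[str, int] = {"database": 0, "computed": 0}
    for e in edges:
        by_prov[e.provenance] += 1
    report["n_edges"] = len(edges)
    report["edges_by_provenance"] = by_prov
    report["n_subnetworks"] = len(subnets)
    report["final_mse"] = results.mse if results is not None else None
    report["top_regulators"] = (
        regulators.head(10).to_dict("records") if len(regulators) else []
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run_from_manifest(manifest_path: str | Path, outdir: str | None = None) -> dict[str, Any]:
    """Re-run a pipeline exactly as recorded in a manifest."""
    with open(manifest_path) as fh:
        raw = json.load(fh)
    if outdir is not None:
        raw["outdir"] = outdir
    config = validate_config(raw)
    return run_pipeline(config)
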