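"""End-to-end orchestration: screen → propagate → intersect → module → hubs → ORA.

Each stage writes its outputs under the run directory and the run
manifest captures every parameter and every set cardinality, so a run
can be audited (and reproduced) from the manifest alone.  The demo mode
generates a synthetic study with planted truth and pushes it through the
same code path as real data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import de, io, mcode, ora, rwr, synth, venn
from .de import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one pipeline run.

    Defaults are the analysis' canonical values: |logFC| > 0.585 with
    FDR < 0.05 for the screen, edge confidence > 0.400, restart 0.7 with
    L1 tolerance 1e-5 for the propagation, MCODE node-score cutoff 0.2
    with haircut, hub degree > 10, and p < 0.05 with q < 0.05 for the
    enrichment.
    """

    expression_path: str
    samples_path: str
    edges_path: str
    output_dir: str
    gmt_path: str | None = None
    case_group: str = "SNI"
    control_group: str = "Sham"
    test_method: str = "moderated_t"  # or "t" for the ordinary pooled t
    lfc_threshold: float = de.DEFAULT_LFC_THRESHOLD
    fdr_threshold: float = de.DEFAULT_FDR_THRESHOLD
    confidence_threshold: float = rwr.DEFAULT_CONFIDENCE_THRESHOLD
    restart: float = rwr.DEFAULT_RESTART
    tolerance: float = rwr.DEFAULT_TOLERANCE
    max_iterations: int = 10_000
    norm: str = "l1"
    top_k: int = 35
    node_score_cutoff: float = mcode.DEFAULT_NODE_SCORE_CUTOFF
    haircut: bool = True
    k_core: int = mcode.DEFAULT_KCORE
    degree_threshold: int = mcode.DEFAULT_DEGREE_THRESHOLD
    hub_context: str = "module"  # or "candidate_network"
    p_threshold: float = ora.DEFAULT_P_THRESHOLD
    q_threshold: float = ora.DEFAULT_Q_THRESHOLD
    min_id_overlap: int = 1

    def __post_init__(self) -> None:
        positive = {
            "lfc_threshold": self.lfc_threshold,
            "fdr_threshold": self.fdr_threshold,
            "confidence_threshold": self.confidence_threshold,
            "tolerance": self.tolerance,
            "p_threshold": self.p_threshold,
            "q_threshold": self.q_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if not 0.0 < self.restart <= 1.0:
            raise ValidationError("restart must be in (0, 1]")
        if self.hub_context not in ("module", "candidate_network"):
            raise ValidationError("hub_context must be 'module' or 'candidate_network'")
        if self.test_method not in ("moderated_t", "t"):
            raise ValidationError("test_method must be 'moderated_t' or 't'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    """In-memory results of a pipeline run plus the written manifest."""

    manifest: dict
    deg_sets: dict[str, set[str]]
    candidate_sets: dict[str, set[str]]
    common_genes: set[str]
    modules: list[mcode.ModuleResult]
    hubs: list[mcode.HubCall]
    enrichment: pd.DataFrame | None
    output_dir: Path

    @property
    def top_module(self) -> mcode.ModuleResult | None:
        return self.modules[0] if self.modules else None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage on the configured inputs.

    Raises on unreadable inputs or an id-space mismatch between the
    expression matrix and the network before any output is written.
    """
    for label, path in (
        ("expression", config.expression_path),
        ("sample sheet", config.samples_path),
        ("edge list", config.edges_path),
        ("GMT", config.gmt_path),
    ):
        if path is not None and not Path(path).is_file():
            raise ValidationError(f"{label} file not found: {path}")
    experiment = io.read_expression(config.expression_path, config.samples_path)
    network = rwr.load_network(config.edges_path, config.confidence_threshold)
    overlap = set(experiment.gene_ids) & set(network.nodes)
    if len(overlap) < config.min_id_overlap:
        raise ValidationError(
            f"expression and network share only {len(overlap)} gene id(s) "
            f"(floor {config.min_id_overlap}); check that both use the same id space"
        )
    outdir = Path(config.output_dir)
    for sub in ("de", "rwr", "intersect", "module", "enrichment"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    transition = rwr.column_normalize(network)
    deg_sets: dict[str, set[str]] = {}
    candidate_sets: dict[str, set[str]] = {}
    rwr_manifests: dict[str, dict] = {}
    stat_fn = de.moderated_t_test if config.test_method == "moderated_t" else None
    for tp in experiment.timepoints:
        table = de.de_table(
            experiment,
            tp,
            case_group=config.case_group,
            control_group=config.control_group,
            lfc_threshold=config.lfc_threshold,
            fdr_threshold=config.fdr_threshold,
            stat_fn=stat_fn,
        )
        table.to_csv(outdir / "de" / f"{tp}_de.tsv", sep="\t", index_label="gene")
        seeds = de.screen_degs(table, config.lfc_threshold, config.fdr_threshold)
        deg_sets[tp] = seeds
        logger.info("%s: %d DEG(s) pass the screen", tp, len(seeds))
        result = rwr.rwr_from_seeds(
            transition,
            seeds,
            restart=config.restart,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
            norm=config.norm,
        )
        ranking = rwr.ranking_table(result, seeds)
        ranking.to_csv(outdir / "rwr" / f"{tp}_ranking.tsv", sep="\t")
        rwr_manifests[tp] = result.manifest()
        (outdir / "rwr" / f"{tp}_manifest.json").write_text(
            json.dumps(rwr_manifests[tp], indent=2) + "\n"
        )
        candidate_sets[tp] = rwr.select_candidates(result, seeds, config.top_k)
        io.write_gene_list(candidate_sets[tp], outdir / "rwr" / f"{tp}_candidates.txt")

    intersection = venn.intersect_sets(candidate_sets)
    io.write_gene_list(intersection.common, outdir / "intersect" / "common_genes.txt")
    (outdir / "intersect" / "venn_regions.json").write_text(
        json.dumps(intersection.regions, indent=2, sort_keys=True) + "\n"
    )

    modules: list[mcode.ModuleResult] = []
    hubs: list[mcode.HubCall] = []
    candidate_network = None
    if intersection.common:
        candidate_network = mcode.induced_subgraph(network, intersection.common)
        modules = mcode.mcode_find_modules(
            candidate_network,
            node_score_cutoff=config.node_score_cutoff,
            haircut=config.haircut,
            k_core=config.k_core,
        )
    if modules:
        top = modules[0]
        io.write_gene_list(top.members, outdir / "module" / "module_members.txt")
        with (outdir / "module" / "module_edges.tsv").open("w") as handle:
            handle.write("gene1\tgene2\n")
            for a, b in top.edge_list():
                handle.write(f"{a}\t{b}\n")
        hub_graph = top.graph if config.hub_context == "module" else candidate_network
        hubs = mcode.call_hubs(hub_graph, config.degree_threshold, config.hub_context)
        with (outdir / "module" / "hubs.tsv").open("w") as handle:
            handle.write("gene\tdegree\tcontext\n")
            for call in hubs:
                handle.write(f"{call.gene}\t{call.degree}\t{call.context}\n")
    else:
        logger.warning("no dense module found; hub calling skipped")

    enrichment_table = None
    if config.gmt_path and intersection.common:
        universe = set(network.nodes)
        collection = ora.read_gmt(config.gmt_path, universe)
        enrichment_table = ora.ora_test(
            intersection.common & universe,
            collection,
            p_threshold=config.p_threshold,
            q_threshold=config.q_threshold,
        )
        enrichment_table.to_csv(
            outdir / "enrichment" / "enrichment.tsv", sep="\t", index=False
        )

    manifest = {
        "parameters": config.to_dict(),
        "network": {
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
            "expression_overlap": len(overlap),
        },
        "rwr": rwr_manifests,
        "cardinalities": {
            "degs_per_timepoint": {tp: len(s) for tp, s in deg_sets.items()},
            "candidates_per_timepoint": {tp: len(s) for tp, s in candidate_sets.items()},
            "intersection": len(intersection.common),
            "module_size": modules[0].size if modules else 0,
            "module_score": modules[0].score if modules else 0.0,
            "n_modules": len(modules),
            "hub_count": len(hubs),
        },
        "venn_regions": intersection.regions,
        "hubs": [{"gene": h.gene, "degree": h.degree, "context": h.context} for h in hubs],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunReport(
        manifest=manifest,
        deg_sets=deg_sets,
        candidate_sets=candidate_sets,
        common_genes=intersection.common,
        modules=modules,
        hubs=hubs,
        enrichment=enrichment_table,
        output_dir=outdir,
    )


def write_study_inputs(study: synth.SyntheticStudy, input_dir) -> dict[str, str]:
    """Serialize a synthetic study to the pipeline's on-disk input formats."""
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(input_dir / "expression.tsv"),
        "samples": str(input_dir / "samples.tsv"),
        "edges": str(input_dir / "edges.tsv"),
        "ground_truth": str(input_dir / "ground_truth.json"),
    }
    io.write_expression(study.experiment, paths["expression"], paths["samples"])
    io.write_string_edges(study.network, paths["edges"])
    study.truth.to_json(paths["ground_truth"])
    return paths


def run_demo(
    seed: int,
    output_dir,
    alias_hubs: bool = False,
    **study_kwargs,
) -> tuple[RunReport, synth.GroundTruth]:
    """Generate a planted-truth study and run the full pipeline on it.

    Inputs land in ``output_dir/inputs``, stage outputs in
    ``output_dir/run``.  Extra keyword arguments go straight to
    :func:`walkhub.synth.generate_study`.
    """
    output_dir = Path(output_dir)
    study = synth.generate_study(seed, alias_hubs=alias_hubs, **study_kwargs)
    paths = write_study_inputs(study, output_dir / "inputs")
    config = PipelineConfig(
        expression_path=paths["expression"],
        samples_path=paths["samples"],
        edges_path=paths["edges"],
        output_dir=str(output_dir / "run"),
        case_group=study.design.case_group,
        control_group=study.design.control_group,
    )
    report = run_pipeline(config)
    report.manifest["demo_seed"] = seed
    return report, study.truth
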