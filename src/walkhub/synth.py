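"""Synthetic expression experiments and PPI networks with planted truth.

The generator emulates the design of a nerve-injury microarray study:
two groups (SNI case vs Sham control), three replicates per group at
three timepoints (days 3, 7, 21 post-surgery), Gaussian noise around a
constant baseline log2 intensity, and a planted set of up-regulated
genes per timepoint whose shared core is what the intersection stage
should recover.  The companion network generator builds a scale-free
background by preferential attachment and overlays one planted dense
module containing designated hub genes, so the module-extraction and
hub-calling stages also have a known answer.

Everything is deterministic given the seed; tests and the demo pipeline
rely on that.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .de import ExpressionExperiment, ValidationError

logger = logging.getLogger(__name__)

#: Arbitrary but fixed baseline: only differences matter downstream.
BASELINE_LOG2 = 8.0

#: Rat gene symbols that can be aliased onto planted hubs for readable demos.
DEMO_HUB_SYMBOLS = ("C3", "C1qb", "Ccl2", "Cxcl13", "Timp1", "Fcgr2b", "Gal", "Lyz2")


def gene_universe(n_genes: int) -> list[str]:
    """Synthetic gene ids G000001..G{n} (zero-padded, lexicographically ordered)."""
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class ExperimentDesign:
    """Two-group multi-timepoint design with equal replication."""

    n_genes: int = 2000
    timepoints: tuple[str, ...] = ("d3", "d7", "d21")
    replicates_per_group: int = 3
    groups: tuple[str, str] = ("SNI", "Sham")

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not self.timepoints or len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("timepoints must be non-empty and unique")
        if self.replicates_per_group < 2:
            raise ValidationError("need >=2 replicates per group for a variance estimate")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValidationError("exactly two distinct group labels required")

    @property
    def case_group(self) -> str:
        return self.groups[0]

    @property
    def control_group(self) -> str:
        return self.groups[1]


@dataclass(frozen=True)
class PlantedSignal:
    """Which genes are shifted, where, and by how much."""

    de_genes_per_timepoint: dict[str, frozenset[str]]
    effect_size: float
    noise_sd: float
    common_core: frozenset[str]

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for tp, genes in self.de_genes_per_timepoint.items():
            if not self.common_core <= genes:
                raise ValidationError(
                    f"common_core must be planted at every timepoint; missing at {tp!r}"
                )


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Scale-free background plus one planted dense module.

    When ``hub_genes`` is non-empty, each hub is wired to every other
    module member deterministically (guaranteeing the hubs' high
    within-module degree) and the remaining member pairs are sampled
    i.i.d. at a rate chosen so the expected module density meets
    ``module_density``.  With no hubs declared, all member pairs are
    sampled i.i.d. at ``module_density``.
    """

    n_nodes: int
    planted_module_genes: frozenset[str] = frozenset()
    module_density: float = 0.9
    background_attachment: int = 2
    confidence_range: tuple[int, int] = (500, 999)
    rng_seed: int = 0
    hub_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValidationError("n_nodes must be positive")
        m = len(self.planted_module_genes)
        if m and not 3 <= m <= self.n_nodes:
            raise ValidationError("planted module needs 3..n_nodes genes")
        if not 0.0 < self.module_density <= 1.0:
            raise ValidationError("module_density must be in (0, 1]")
        if m >= 2 and self.module_density * m * (m - 1) / 2 < m - 1:
            raise ValidationError(
                "module_density too low for the module to be connected in expectation"
            )
        if self.background_attachment < 1:
            raise ValidationError("background_attachment must be positive")
        lo, hi = self.confidence_range
        if not 0 <= lo <= hi <= 1000:
            raise ValidationError("confidence_range must be within [0, 1000]")
        if not self.hub_genes <= self.planted_module_genes:
            raise ValidationError("hub_genes must be a subset of the planted module")


@dataclass
class GroundTruth:
    """What the generator planted, for tests and reports only."""

    signal: PlantedSignal
    module_members: frozenset[str]
    hub_genes: frozenset[str]
    rng_seed: int

    def __post_init__(self) -> None:
        if not self.hub_genes <= (self.module_members & self.signal.common_core):
            raise ValidationError(
                "planted hubs must lie in the module and in the common core"
            )

    def to_json(self, path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "effect_size": self.signal.effect_size,
            "noise_sd": self.signal.noise_sd,
            "common_core": sorted(self.signal.common_core),
            "de_genes_per_timepoint": {
                tp: sorted(genes)
                for tp, genes in self.signal.de_genes_per_timepoint.items()
            },
            "module_members": sorted(self.module_members),
            "hub_genes": sorted(self.hub_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        signal = PlantedSignal(
            de_genes_per_timepoint={
                tp: frozenset(genes)
                for tp, genes in payload["de_genes_per_timepoint"].items()
            },
            effect_size=payload["effect_size"],
            noise_sd=payload["noise_sd"],
            common_core=frozenset(payload["common_core"]),
        )
        return cls(
            signal=signal,
            module_members=frozenset(payload["module_members"]),
            hub_genes=frozenset(payload["hub_genes"]),
            rng_seed=payload["rng_seed"],
        )


def generate_expression(
    design: ExperimentDesign, signal: PlantedSignal, seed: int
) -> ExpressionExperiment:
    """Baseline + Gaussian noise, with case-group shifts for planted genes.

    Deterministic given the seed: the same (design, signal, seed) triple
    yields a bit-identical matrix.
    """
    genes = gene_universe(design.n_genes)
    universe = set(genes)
    for tp, planted in signal.de_genes_per_timepoint.items():
        unknown = planted - universe
        if unknown:
            raise ValidationError(
                f"planted gene(s) outside the {design.n_genes}-gene universe "
                f"at {tp!r}: {sorted(unknown)[:5]}"
            )
        if tp not in design.timepoints:
            raise ValidationError(f"planted timepoint {tp!r} not in the design")
    sample_ids, groups, timepoints = [], [], []
    for tp in design.timepoints:
        for group in design.groups:
            for rep in range(1, design.replicates_per_group + 1):
                sample_ids.append(f"{group}_{tp}_r{rep}")
                groups.append(group)
                timepoints.append(tp)
    rng = np.random.default_rng(seed)
    values = BASELINE_LOG2 + rng.normal(
        0.0, signal.noise_sd, size=(design.n_genes, len(sample_ids))
    )
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    samples = pd.DataFrame(
        {"group": groups, "timepoint": timepoints},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    for tp, planted in signal.de_genes_per_timepoint.items():
        case_cols = [
            j
            for j, sid in enumerate(sample_ids)
            if samples.loc[sid, "timepoint"] == tp
            and samples.loc[sid, "group"] == design.case_group
        ]
        rows = [gene_pos[g] for g in sorted(planted)]
        frame.iloc[rows, case_cols] += signal.effect_size
    return ExpressionExperiment(values=frame, samples=samples)


def generate_ppi(spec: SyntheticNetworkSpec) -> nx.Graph:
    """Scale-free background with one planted dense module.

    Background edges between two module members are dropped before the
    planted edges go in, so the within-module topology is exactly the
    planted one.  Every edge gets an integer ``combined_score`` sampled
    uniformly from ``confidence_range`` (and ``confidence`` = score/1000).
    """
    nodes = gene_universe(spec.n_nodes)
    universe = set(nodes)
    module = sorted(spec.planted_module_genes)
    if not set(module) <= universe:
        raise ValidationError("planted module genes outside the node universe")
    rng = np.random.default_rng(spec.rng_seed)
    ba_seed = int(rng.integers(0, 2**31))
    if spec.n_nodes > spec.background_attachment:
        background = nx.barabasi_albert_graph(
            spec.n_nodes, spec.background_attachment, seed=ba_seed
        )
    else:
        background = nx.complete_graph(spec.n_nodes)
    graph: nx.Graph = nx.relabel_nodes(background, dict(enumerate(nodes)))
    module_set = set(module)
    graph.remove_edges_from(
        [(a, b) for a, b in list(graph.edges) if a in module_set and b in module_set]
    )
    if module:
        _plant_module(graph, module, spec, rng)
        non_module = universe - module_set
        wired = any(
            (set(graph[g]) - module_set) for g in module
        )
        if non_module and not wired:
            graph.add_edge(min(module), min(non_module))
    lo, hi = spec.confidence_range
    for a, b in sorted(graph.edges):
        score = int(rng.integers(lo, hi + 1))
        graph[a][b]["combined_score"] = score
        graph[a][b]["confidence"] = score / 1000.0
    return graph


def _plant_module(
    graph: nx.Graph, module: list[str], spec: SyntheticNetworkSpec, rng: np.random.Generator
) -> None:
    hubs = sorted(spec.hub_genes)
    hub_set = set(hubs)
    m = len(module)
    all_pairs = m * (m - 1) // 2
    forced = [
        (a, b)
        for i, a in enumerate(module)
        for b in module[i + 1 :]
        if a in hub_set or b in hub_set
    ]
    free = [
        (a, b)
        for i, a in enumerate(module)
        for b in module[i + 1 :]
        if a not in hub_set and b not in hub_set
    ]
    graph.add_edges_from(forced)
    if hubs:
        target_extra = spec.module_density * all_pairs - len(forced)
        p_free = min(1.0, max(0.0, target_extra / len(free))) if free else 0.0
    else:
        p_free = spec.module_density
    if free and p_free > 0:
        draws = rng.random(len(free))
        graph.add_edges_from(pair for pair, u in zip(free, draws) if u < p_free)


def make_planted_signal(
    design: ExperimentDesign,
    seed: int,
    n_de_per_timepoint: int = 60,
    n_core: int = 40,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
) -> PlantedSignal:
    """Random planted DE sets: a shared core plus disjoint per-timepoint extras.

    Defaults (60 DE genes per timepoint, 40 shared) loosely mirror the
    per-timepoint DEG counts and intersection size seen in nerve-injury
    expression screens.
    """
    if n_core > n_de_per_timepoint:
        raise ValidationError("core cannot exceed the per-timepoint DE count")
    n_extra = n_de_per_timepoint - n_core
    needed = n_core + n_extra * len(design.timepoints)
    if needed > design.n_genes:
        raise ValidationError(
            f"design has {design.n_genes} genes but the signal needs {needed}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(design.n_genes, size=needed, replace=False)
    genes = gene_universe(design.n_genes)
    picked = [genes[i] for i in chosen]
    core = frozenset(picked[:n_core])
    per_tp: dict[str, frozenset[str]] = {}
    offset = n_core
    for tp in design.timepoints:
        extras = frozenset(picked[offset : offset + n_extra])
        per_tp[tp] = core | extras
        offset += n_extra
    return PlantedSignal(
        de_genes_per_timepoint=per_tp,
        effect_size=effect_size,
        noise_sd=noise_sd,
        common_core=core,
    )


@dataclass
class SyntheticStudy:
    """A full simulated study: expression, network, and what was planted."""

    experiment: ExpressionExperiment
    network: nx.Graph
    truth: GroundTruth
    design: ExperimentDesign = field(default_factory=ExperimentDesign)


def generate_study(
    seed: int,
    design: ExperimentDesign | None = None,
    n_de_per_timepoint: int = 60,
    n_core: int = 40,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    module_size: int = 12,
    n_hubs: int = 8,
    module_density: float = 0.9,
    background_attachment: int = 2,
    confidence_range: tuple[int, int] = (500, 999),
    alias_hubs: bool = False,
) -> SyntheticStudy:
    """One coherent study with a recoverable planted answer at every stage.

    The planted module lives inside the common core (so it survives the
    intersection), the hubs inside the module.  The network shares the
    expression experiment's gene universe.  ``alias_hubs`` relabels the
    planted hubs to familiar rat symbols for demo readability.
    """
    design = design or ExperimentDesign()
    if n_hubs > module_size:
        raise ValidationError("cannot plant more hubs than module members")
    if module_size > n_core:
        raise ValidationError("planted module must fit inside the common core")
    rng = np.random.default_rng(seed)
    signal_seed, expr_seed, net_seed = (
        int(x) for x in rng.integers(0, 2**31, size=3)
    )
    signal = make_planted_signal(
        design,
        signal_seed,
        n_de_per_timepoint=n_de_per_timepoint,
        n_core=n_core,
        effect_size=effect_size,
        noise_sd=noise_sd,
    )
    core = sorted(signal.common_core)
    module_idx = rng.choice(len(core), size=module_size, replace=False)
    module = frozenset(core[i] for i in module_idx)
    hubs = frozenset(sorted(module)[:n_hubs])
    experiment = generate_expression(design, signal, expr_seed)
    net_spec = SyntheticNetworkSpec(
        n_nodes=design.n_genes,
        planted_module_genes=module,
        module_density=module_density,
        background_attachment=background_attachment,
        confidence_range=confidence_range,
        rng_seed=net_seed,
        hub_genes=hubs,
    )
    network = generate_ppi(net_spec)
    truth = GroundTruth(
        signal=signal, module_members=module, hub_genes=hubs, rng_seed=seed
    )
    study = SyntheticStudy(
        experiment=experiment, network=network, truth=truth, design=design
    )
    if alias_hubs:
        _alias_hubs(study)
    return study


def _alias_hubs(study: SyntheticStudy) -> None:
    """Rename planted hub ids to familiar rat gene symbols, in place."""
    hubs = sorted(study.truth.hub_genes)
    mapping = dict(zip(hubs, DEMO_HUB_SYMBOLS))
    study.experiment.values.rename(index=mapping, inplace=True)
    study.network = nx.relabel_nodes(study.network, mapping)
    signal = study.truth.signal
    new_signal = PlantedSignal(
        de_genes_per_timepoint={
            tp: frozenset(mapping.get(g, g) for g in genes)
            for tp, genes in signal.de_genes_per_timepoint.items()
        },
        effect_size=signal.effect_size,
        noise_sd=signal.noise_sd,
        common_core=frozenset(mapping.get(g, g) for g in signal.common_core),
    )
    study.truth = GroundTruth(
        signal=new_signal,
        module_members=frozenset(
            mapping.get(g, g) for g in study.truth.module_members
        ),
        hub_genes=frozenset(mapping.values()),
        rng_seed=study.truth.rng_seed,
    )
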