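"""Dense-module extraction (MCODE-style) and degree-based hub calling.

Each node is weighted by the densest k-core of its closed neighbourhood:
weight(v) = k_max * density(highest k-core of G[N(v) ∪ {v}]).  Modules
grow greedily outward from the highest-weight unused node, admitting
neighbours whose weight stays within ``node_score_cutoff`` of the seed's,
then a haircut prunes singly-connected members and modules that do not
contain a 2-core are discarded.  A module's score is density x size, and
hub genes are the module members whose degree strictly exceeds a
threshold (10 by default) in the chosen context graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .de import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_NODE_SCORE_CUTOFF = 0.2
DEFAULT_DEGREE_THRESHOLD = 10
DEFAULT_KCORE = 2


def induced_subgraph(network: nx.Graph, genes: set[str]) -> nx.Graph:
    """Subgraph induced on genes ∩ nodes; missing genes are logged."""
    if not genes:
        raise ValidationError("empty gene set")
    present = genes & set(network.nodes)
    if not present:
        raise ValidationError("none of the requested genes is in the network")
    missing = genes - present
    if missing:
        logger.info("%d gene(s) absent from the network: %s", len(missing), sorted(missing)[:10])
    return network.subgraph(present).copy()


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def mcode_node_weights(graph: nx.Graph) -> dict[str, float]:
    """Core-weighted local density per node.

    A node whose closed neighbourhood is a 4-clique gets 3.0 (3-core of
    density 1); an isolated node gets 0; a leaf whose neighbourhood is a
    single edge gets 1.0 (1-core of density 1) — the minimal positive
    weight by this convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    weights: dict[str, float] = {}
    for v in graph:
        closed = set(graph[v]) | {v}
        nbhd = graph.subgraph(closed)
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(nbhd)
        k_max = max(core.values())
        top_core = nbhd.subgraph([u for u, k in core.items() if k >= k_max])
        weights[v] = k_max * _density(top_core)
    return weights


def _haircut(graph: nx.Graph) -> nx.Graph:
    """Iteratively strip degree-1 nodes (idempotent by construction)."""
    pruned = graph.copy()
    while True:
        leaves = [v for v in pruned if pruned.degree(v) == 1]
        if not leaves:
            return pruned
        pruned.remove_nodes_from(leaves)


@dataclass
class ModuleResult:
    """A scored dense subgraph of the candidate-gene network."""

    members: list[str]
    graph: nx.Graph
    score: float
    density: float
    seed: str
    node_weights: dict[str, float]

    @property
    def size(self) -> int:
        return len(self.members)

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def _score(graph: nx.Graph) -> float:
    return _density(graph) * graph.number_of_nodes()


def mcode_find_modules(
    graph: nx.Graph,
    node_score_cutoff: float = DEFAULT_NODE_SCORE_CUTOFF,
    haircut: bool = True,
    fluff: bool = False,
    k_core: int = DEFAULT_KCORE,
) -> list[ModuleResult]:
    """Ranked dense modules by seeded greedy expansion.

    Modules are disjoint (a gene joins at most one emitted module) and
    ranked by score descending, ties broken by larger size then by
    lexicographically smallest member.  ``fluff`` is accepted for
    interface compatibility but not implemented (off is the default in
    the Cytoscape plugin too).
    """
    if fluff:
        raise NotImplementedError("fluff expansion is not supported")
    if graph.number_of_nodes() == 0:
        return []
    weights = mcode_node_weights(graph)
    order = sorted(graph, key=lambda v: (-weights[v], v))
    used: set[str] = set()
    modules: list[ModuleResult] = []
    for seed in order:
        if seed in used or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        stack = [seed]
        while stack:
            v = stack.pop()
            for u in sorted(graph[v]):
                if u in used or u in members:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    stack.append(u)
        sub = graph.subgraph(members).copy()
        if haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() < 3:
            continue
        if max(nx.core_number(sub).values()) < k_core:
            continue
        used |= set(sub.nodes)
        modules.append(
            ModuleResult(
                members=sorted(sub.nodes),
                graph=sub,
                score=_score(sub),
                density=_density(sub),
                seed=seed,
                node_weights={v: weights[v] for v in sub.nodes},
            )
        )
    modules.sort(key=lambda m: (-m.score, -m.size, min(m.members)))
    return modules


@dataclass
class HubCall:
    gene: str
    degree: int
    context: str  # which graph the degree was computed in


def call_hubs(
    graph: nx.Graph,
    degree_threshold: int = DEFAULT_DEGREE_THRESHOLD,
    context: str = "module",
) -> list[HubCall]:
    """Genes with degree strictly greater than the threshold.

    Sorted by degree descending, then gene id.  ``context`` only labels
    the output — pass the module's induced subgraph or the full candidate
    subnetwork depending on where the degree should be measured.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    calls = [
        HubCall(gene=v, degree=d, context=context)
        for v, d in graph.degree
        if d > degree_threshold
    ]
    calls.sort(key=lambda h: (-h.degree, h.gene))
    return calls
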