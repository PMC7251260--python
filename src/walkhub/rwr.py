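"""Random walk with restart (RWR) over a protein-protein interaction graph.

The walker starts from a uniform distribution over m seed genes (mass 1/m
each) and at every step either moves to a uniformly chosen neighbour of
its current node (probability 1-r) or restarts at the seed distribution
(probability r):

    P_{t+1} = (1 - r) A' P_t + r P_0

where A' is the column-normalized binary adjacency matrix, so A'[i, j] =
A[i, j] / deg(j) and every column sums to one.  Iteration stops when the
difference between consecutive probability vectors (L1 norm by default)
drops below the tolerance, 1e-5 by default.  The fixed point ranks every
node in the network by proximity to the seed set; the top non-seed nodes
become new candidate genes.

Edges enter the analysis only if their STRING-style confidence strictly
exceeds 0.400 (combined_score > 400), and the graph is restricted to its
largest connected component so the transition matrix has no zero column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from . import io
from .de import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.400
DEFAULT_RESTART = 0.7
DEFAULT_TOLERANCE = 1e-5

_NORMS = {
    "l1": lambda v: float(np.abs(v).sum()),
    "l2": lambda v: float(np.sqrt((v * v).sum())),
    "max": lambda v: float(np.abs(v).max()),
}


def filter_network(
    graph: nx.Graph, confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> nx.Graph:
    """Drop edges at or below the confidence threshold, keep the largest component.

    The strict inequality matters: an edge with combined_score exactly 400
    (confidence 0.400) is discarded.
    """
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        if data.get("confidence", 1.0) > confidence_threshold:
            kept.add_edge(a, b, **data)
    kept.remove_nodes_from([n for n in kept if kept.degree(n) == 0])
    if kept.number_of_nodes() == 0:
        raise ValidationError(
            f"no edges survive the confidence > {confidence_threshold} filter"
        )
    components = sorted(nx.connected_components(kept), key=lambda c: (-len(c), min(c)))
    largest = kept.subgraph(components[0]).copy()
    logger.info(
        "confidence > %.3f filter: %d/%d edges kept; largest component %d/%d nodes",
        confidence_threshold,
        kept.number_of_edges(),
        graph.number_of_edges(),
        largest.number_of_nodes(),
        graph.number_of_nodes(),
    )
    return largest


def load_network(
    edge_list_path, confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> nx.Graph:
    """Read a STRING-dialect edge list and apply the confidence filter."""
    return filter_network(io.read_string_edges(edge_list_path), confidence_threshold)


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix plus its node ordering."""

    matrix: sparse.csc_matrix
    nodes: list[str]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.nodes)}


def column_normalize(graph: nx.Graph, weighted: bool = False) -> TransitionMatrix:
    """Build A' with A'[i, j] = A[i, j] / deg(j) (column sums one).

    With ``weighted=True`` the confidence scores replace the binary
    adjacency and columns are normalized by weighted degree; the default
    is the binary adjacency, since the filter is the only use the
    confidences get.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValidationError("empty network")
    weight = "confidence" if weighted else None
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=weight, format="csc")
    adj = adj.astype(float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(col_sums == 0):
        raise RuntimeError("zero-degree node reached column_normalize; filter first")
    matrix = adj @ sparse.diags(1.0 / col_sums)
    return TransitionMatrix(matrix=sparse.csc_matrix(matrix), nodes=nodes)


def make_seed_vector(seeds: set[str], transition: TransitionMatrix) -> np.ndarray:
    """Uniform probability 1/m over the m seeds present in the network.

    Seeds missing from the network are dropped with a warning; the mass is
    spread uniformly over the ones that remain.
    """
    retained = sorted(s for s in seeds if s in transition.index)
    dropped = sorted(set(seeds) - set(retained))
    if not retained:
        raise ValidationError(f"no seed gene is in the network: {sorted(seeds)}")
    if dropped:
        logger.warning("%d seed(s) absent from network, dropped: %s", len(dropped), dropped)
    p0 = np.zeros(len(transition.nodes))
    p0[[transition.index[s] for s in retained]] = 1.0 / len(retained)
    return p0


@dataclass
class RWRResult:
    """Converged propagation vector with its run metadata."""

    probabilities: pd.Series
    restart: float
    seeds_used: list[str]
    seeds_dropped: list[str]
    iterations: int
    final_difference: float
    converged: bool
    tolerance: float
    norm: str
    probability_sums: list[float] = field(default_factory=list, repr=False)
    differences: list[float] = field(default_factory=list, repr=False)

    def manifest(self) -> dict:
        return {
            "restart": self.restart,
            "tolerance": self.tolerance,
            "norm": self.norm,
            "iterations": self.iterations,
            "final_difference": self.final_difference,
            "converged": self.converged,
            "n_seeds_used": len(self.seeds_used),
            "seeds_dropped": self.seeds_dropped,
        }


def propagate(
    transition: TransitionMatrix,
    p0: np.ndarray,
    restart: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = 10_000,
    norm: str = "l1",
    seeds_used: list[str] | None = None,
    seeds_dropped: list[str] | None = None,
) -> RWRResult:
    """Iterate P_{t+1} = (1-r) A' P_t + r P_0 to convergence.

    Returns the first iterate whose difference from its predecessor falls
    strictly below ``tolerance`` in the chosen norm.  Because A' is
    column-stochastic and the update is a convex combination, every
    iterate sums to one; the recorded ``probability_sums`` let callers
    check this invariant per iteration.
    """
    if not 0.0 < restart <= 1.0:
        raise ValidationError(f"restart probability must be in (0, 1], got {restart}")
    if norm not in _NORMS:
        raise ValidationError(f"norm must be one of {sorted(_NORMS)}")
    if not np.isclose(p0.sum(), 1.0):
        raise ValidationError("seed vector must sum to 1")
    diff = _NORMS[norm]
    matrix = transition.matrix
    p = p0.copy()
    sums: list[float] = [float(p.sum())]
    deltas: list[float] = []
    delta = np.inf
    iterations = 0
    converged = False
    for iterations in range(1, max_iterations + 1):
        p_next = (1.0 - restart) * (matrix @ p) + restart * p0
        delta = diff(p_next - p)
        p = p_next
        sums.append(float(p.sum()))
        deltas.append(delta)
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RWR did not converge in {max_iterations} iterations "
            f"(last {norm} difference {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return RWRResult(
        probabilities=pd.Series(p, index=transition.nodes, name="probability"),
        restart=restart,
        seeds_used=seeds_used or [],
        seeds_dropped=seeds_dropped or [],
        iterations=iterations,
        final_difference=delta,
        converged=converged,
        tolerance=tolerance,
        norm=norm,
        probability_sums=sums,
        differences=deltas,
    )


def rwr_from_seeds(
    transition: TransitionMatrix,
    seeds: set[str],
    restart: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = 10_000,
    norm: str = "l1",
) -> RWRResult:
    """Convenience wrapper: build the seed vector then propagate."""
    retained = sorted(s for s in seeds if s in transition.index)
    dropped = sorted(set(seeds) - set(retained))
    p0 = make_seed_vector(seeds, transition)
    return propagate(
        transition,
        p0,
        restart=restart,
        tolerance=tolerance,
        max_iterations=max_iterations,
        norm=norm,
        seeds_used=retained,
        seeds_dropped=dropped,
    )


def closed_form_oracle(
    transition: TransitionMatrix, p0: np.ndarray, restart: float
) -> np.ndarray:
    """Exact fixed point of the propagation update by a dense linear solve.

    Solves (I - (1-r) A') P = r P_0.  Verification only: the dense solve
    is O(n^3) and intended for graphs of at most a few thousand nodes.
    """
    if not 0.0 < restart <= 1.0:
        raise ValidationError(f"restart probability must be in (0, 1], got {restart}")
    n = len(transition.nodes)
    system = np.eye(n) - (1.0 - restart) * transition.matrix.toarray()
    return np.linalg.solve(system, restart * p0)


def select_candidates(
    result: RWRResult, seeds: set[str], top_k: int
) -> set[str]:
    """Seeds (those in the network) plus the top_k hottest non-seed genes.

    Ties in probability are broken by lexicographic gene id so the
    selection is deterministic.
    """
    if top_k < 0:
        raise ValidationError("top_k must be non-negative")
    in_network = {g for g in seeds if g in result.probabilities.index}
    non_seed = result.probabilities.drop(index=sorted(in_network))
    if top_k > len(non_seed):
        logger.warning(
            "top_k=%d exceeds the %d non-seed genes; returning all", top_k, len(non_seed)
        )
        top_k = len(non_seed)
    order = sorted(non_seed.items(), key=lambda kv: (-kv[1], kv[0]))
    return in_network | {gene for gene, _ in order[:top_k]}


def ranking_table(result: RWRResult, seeds: set[str]) -> pd.DataFrame:
    """Full propagation ranking: gene, probability, is_seed, rank (1 = hottest)."""
    probs = result.probabilities
    order = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in order]
    return pd.DataFrame(
        {
            "probability": [p for _, p in order],
            "is_seed": [g in seeds for g in genes],
            "rank": np.arange(1, len(genes) + 1),
        },
        index=pd.Index(genes, name="gene"),
    )
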