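"""Shared fixtures: tiny hand-built inputs and one cached demo run."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from walkhub import pipeline
from walkhub.de import ExpressionExperiment


def random_connected_graph(rng: np.random.Generator, n: int, extra_edges: int | None = None) -> nx.Graph:
    """A random connected graph: a uniform random tree plus extra edges."""
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for v in range(1, n):
        graph.add_edge(v, int(rng.integers(0, v)))
    if extra_edges is None:
        extra_edges = n // 2
    for _ in range(extra_edges):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            graph.add_edge(int(a), int(b))
    return nx.relabel_nodes(graph, {i: f"N{i:04d}" for i in range(n)})


@pytest.fixture
def hand_experiment() -> ExpressionExperiment:
    """Four genes, 3 case vs 3 control at one timepoint, fixed values."""
    values = pd.DataFrame(
        {
            "SNI_d3_r1": [9.1, 8.0, 8.5, 7.9],
            "SNI_d3_r2": [9.4, 8.2, 8.4, 8.1],
            "SNI_d3_r3": [9.2, 7.9, 8.6, 8.0],
            "Sham_d3_r1": [8.0, 8.1, 8.5, 8.0],
            "Sham_d3_r2": [8.1, 8.0, 8.4, 8.1],
            "Sham_d3_r3": [7.9, 8.2, 8.6, 7.9],
        },
        index=pd.Index(["Ga", "Gb", "Gc", "Gd"], name="gene"),
    )
    samples = pd.DataFrame(
        {
            "group": ["SNI"] * 3 + ["Sham"] * 3,
            "timepoint": ["d3"] * 6,
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionExperiment(values=values, samples=samples)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run with planted truth, shared across tests."""
    outdir = tmp_path_factory.mktemp("demo")
    report, truth = pipeline.run_demo(seed=1, output_dir=outdir)
    return report, truth


@pytest.fixture
def clique_path_graph() -> nx.Graph:
    """A 6-clique joined by one edge to a 10-node path (16 nodes total)."""
    graph = nx.complete_graph([f"C{i}" for i in range(6)])
    path = [f"P{i}" for i in range(10)]
    nx.add_path(graph, path)
    graph.add_edge("C0", "P0")
    return graph


@pytest.fixture
def two_cliques_graph() -> nx.Graph:
    """Two disjoint cliques of sizes 5 and 7."""
    graph = nx.complete_graph([f"A{i}" for i in range(5)])
    graph = nx.compose(graph, nx.complete_graph([f"B{i}" for i in range(7)]))
    return graph
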