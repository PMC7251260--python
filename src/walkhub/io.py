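"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression: genes-in-rows TSV with a header of sample ids, paired with a
sample sheet TSV (sample_id, group, timepoint).  Networks: STRING-dialect
edge lists (protein1, protein2, combined_score with integer scores in
0-1000).  Gene lists: one id per line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .de import ExpressionExperiment, ValidationError

logger = logging.getLogger(__name__)

STRING_COLUMNS = ("protein1", "protein2", "combined_score")


def read_expression(expression_path, samples_path) -> ExpressionExperiment:
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
    return ExpressionExperiment(values=values, samples=samples)


def write_expression(experiment: ExpressionExperiment, expression_path, samples_path) -> None:
    experiment.values.to_csv(expression_path, sep="\t", index_label="gene")
    experiment.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_string_edges(path) -> nx.Graph:
    """Parse a STRING-dialect TSV into an undirected graph.

    Edge attributes: ``combined_score`` (int, 0-1000) and ``confidence``
    (score/1000).  Malformed rows raise with their line number.  Duplicate
    pairs keep the higher score; self-loops are rejected.
    """
    graph = nx.Graph()
    path = Path(path)
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != STRING_COLUMNS:
            raise ValidationError(
                f"{path}: expected header {STRING_COLUMNS}, got {tuple(header[:3])}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = int(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: combined_score {raw!r} is not an integer"
                ) from None
            if not 0 <= score <= 1000:
                raise ValidationError(f"{path}:{lineno}: score {score} outside 0-1000")
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
            if graph.has_edge(a, b):
                score = max(score, graph[a][b]["combined_score"])
            graph.add_edge(a, b, combined_score=score, confidence=score / 1000.0)
    return graph


def write_string_edges(graph: nx.Graph, path) -> None:
    with Path(path).open("w") as handle:
        handle.write("\t".join(STRING_COLUMNS) + "\n")
        for a, b, data in sorted(graph.edges(data=True)):
            handle.write(f"{a}\t{b}\t{data['combined_score']}\n")


def read_gene_list(path) -> list[str]:
    with Path(path).open() as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with Path(path).open("w") as handle:
        for gene in sorted(genes):
            handle.write(gene + "\n")
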