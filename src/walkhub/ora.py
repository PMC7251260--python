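"""Hypergeometric over-representation analysis against GMT collections.

For a query of q genes drawn from a universe of N, a term with K members
and overlap k is scored with the upper-tail probability
P(X >= k), X ~ Hypergeometric(N, K, q).  q-values are Benjamini-Hochberg
adjusted p-values across all tested terms, and a term passes when both
p < 0.05 and q < 0.05 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import ValidationError, bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_Q_THRESHOLD = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a declared universe.

    Members outside the universe are dropped at construction and the
    drop counts kept in ``dropped``.
    """

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict, init=False)

    def __post_init__(self) -> None:
        if len(self.universe) < 2:
            raise ValidationError("universe must contain at least 2 genes")
        restricted: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            inside = members & self.universe
            n_out = len(members) - len(inside)
            if n_out:
                self.dropped[name] = n_out
            restricted[name] = inside
        total_dropped = sum(self.dropped.values())
        if total_dropped:
            logger.info(
                "dropped %d out-of-universe member(s) across %d set(s)",
                total_dropped,
                len(self.dropped),
            )
        self.sets = restricted


def read_gmt(path, universe: set[str]) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...) into a collection."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT rows need >=3 columns")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, universe=universe, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as handle:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")


def hypergeom_upper_tail(k: int, universe_size: int, term_size: int, query_size: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=universe, K=term, draws=query)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, term_size, query_size))


def ora_test(
    query: set[str],
    collection: GeneSetCollection,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Score every term in the collection against the query gene set.

    Query genes outside the universe are dropped with a warning; an empty
    query after restriction is an error.  Returns one row per term,
    sorted by p-value then term name, with columns term, k, query_size,
    term_size, universe_size, p_value, q_value, passes.
    """
    outside = query - collection.universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(outside),
            sorted(outside)[:10],
        )
    inside = query & collection.universe
    if not inside:
        raise ValidationError("query is empty after restriction to the universe")
    n_universe = len(collection.universe)
    n_query = len(inside)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        k = len(inside & members)
        rows.append(
            {
                "term": name,
                "k": k,
                "query_size": n_query,
                "term_size": len(members),
                "universe_size": n_universe,
                "p_value": hypergeom_upper_tail(k, n_universe, len(members), n_query),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = np.asarray(bh_adjust(table["p_value"].to_numpy()))
        table["passes"] = (table["p_value"] < p_threshold) & (table["q_value"] < q_threshold)
        table = table.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return table
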