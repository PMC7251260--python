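"""Intersection of per-timepoint candidate gene sets (the Venn step).

Genes prioritized at every timepoint are the ones taken forward as
stably injury-associated; the exclusive Venn regions are reported so the
overlap structure can be inspected without plotting anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .de import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class IntersectionResult:
    """Common genes plus exclusive Venn region sizes.

    ``regions`` maps a '&'-joined sorted label combination (e.g.
    ``"d3&d7"``) to the number of genes belonging to exactly those sets.
    Region counts sum to the size of the union.
    """

    common: set[str]
    regions: dict[str, int]
    labels: list[str]


def intersect_sets(candidates: dict[str, set[str]]) -> IntersectionResult:
    """Exact intersection of >=2 labelled gene sets with Venn region counts."""
    if len(candidates) < 2:
        raise ValidationError("need at least 2 candidate sets to intersect")
    labels = list(candidates)
    sets = [candidates[label] for label in labels]
    common = set.intersection(*sets)
    union = set.union(*sets)
    regions: dict[str, int] = {}
    for gene in union:
        membership = "&".join(sorted(label for label in labels if gene in candidates[label]))
        regions[membership] = regions.get(membership, 0) + 1
    if not common:
        logger.warning("candidate sets share no gene; intersection is empty")
    return IntersectionResult(common=common, regions=regions, labels=labels)
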