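"""Lineage monophyly tests on gene trees.

Orthogroup-level duplication calls are validated by asking whether a gene
tree places all tips of each focal lineage in a single clade.  Trees from
maximum-likelihood programs are unrooted, so monophyly is decided on edge
bipartitions: lineage L is monophyletic iff some edge separates exactly the
L tips from the rest.  Tips that map to no focal lineage are pruned
(equivalently, bipartitions are intersected with the mapped tip set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Iterable

import dendropy

from .types import GeneTreeRec, LineageConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonophylyResult:
    orthogroup_id: str | None
    lineage_monophyly: dict[str, bool]
    both_monophyletic: bool
    n_tips: dict[str, int]
    untestable: bool = False


def _bipartitions(tree: dendropy.Tree, mapped: set[str]) -> Iterable[frozenset]:
    """Leaf sets (restricted to mapped tips) below every node of the tree."""
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in mapped
        )
        if leaves:
            yield leaves


def lineage_monophyly(tree: GeneTreeRec, cfg: LineageConfig) -> MonophylyResult:
    """Test whether each focal lineage's tips form a clade on the unrooted tree.

    Lineages with <= 1 tip are trivially monophyletic.  Trees with fewer
    than 3 mapped tips are flagged untestable (and trivially true).  With
    exactly two lineages present the two flags coincide, since each side of
    a separating bipartition is the other's complement.
    """
    lin_a, lin_b = cfg.focal_pair
    tips_by_lineage: dict[str, set[str]] = {lin_a: set(), lin_b: set()}
    unmapped = []
    for tip, sp in tree.tip_species.items():
        ln = cfg.species_to_lineage.get(sp)
        if ln in tips_by_lineage:
            tips_by_lineage[ln].add(tip)
        else:
            unmapped.append(tip)
    if unmapped:
        logger.warning("ignoring %d tip(s) outside the focal lineages: %s",
                       len(unmapped), unmapped)
    mapped = tips_by_lineage[lin_a] | tips_by_lineage[lin_b]
    n_tips = {ln: len(tips_by_lineage[ln]) for ln in (lin_a, lin_b)}

    if len(mapped) < 3:
        flags = {ln: True for ln in (lin_a, lin_b)}
        return MonophylyResult(tree.orthogroup_id, flags, True, n_tips, untestable=True)

    dtree = dendropy.Tree.get(file=StringIO(tree.newick), schema="newick",
                              preserve_underscores=True)
    parts = set(_bipartitions(dtree, mapped))
    flags = {}
    for ln in (lin_a, lin_b):
        tips = frozenset(tips_by_lineage[ln])
        if len(tips) <= 1:
            flags[ln] = True
        else:
            complement = frozenset(mapped - tips)
            flags[ln] = tips in parts or complement in parts
    return MonophylyResult(tree.orthogroup_id, flags,
                           flags[lin_a] and flags[lin_b], n_tips)


def validation_rate(results: Iterable[MonophylyResult]) -> dict:
    """Fraction of testable trees with both lineages monophyletic.

    Untestable trees are excluded from the denominator and counted
    separately; the rate is None when nothing is testable.
    """
    results = list(results)
    if not results:
        raise ValueError("no monophyly results")
    testable = [r for r in results if not r.untestable]
    validated = sum(1 for r in testable if r.both_monophyletic)
    return {
        "n_total": len(results),
        "n_testable": len(testable),
        "n_untestable": len(results) - len(testable),
        "n_validated": validated,
        "rate": validated / len(testable) if testable else None,
    }
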