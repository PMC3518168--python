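"""Monophyly-constrained searches and step-difference reporting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .matrix import CharacterMatrix, TaxonSet
from .search import SearchConfig, SearchResult, tbr_search
from .tree import PhyloTree

__all__ = ["ConstraintSpec", "is_monophyletic", "constrained_search",
           "step_difference"]


@dataclass(frozen=True)
class ConstraintSpec:
    """Taxon sets whose monophyly is enforced jointly.

    Groups must be pairwise disjoint or nested; overlapping groups are
    unsatisfiable and rejected.
    """

    groups: tuple[TaxonSet, ...]

    def __init__(self, groups: Sequence[TaxonSet]):
        object.__setattr__(self, "groups", tuple(groups))
        for i, a in enumerate(self.groups):
            if len(a) < 2:
                raise ValueError(f"group {a.name!r} needs >= 2 members")
            for b in self.groups[i + 1:]:
                inter = a.members & b.members
                if inter and not (a.members <= b.members
                                  or b.members <= a.members):
                    raise ValueError(
                        f"groups {a.name!r} and {b.name!r} overlap without "
                        f"nesting: unsatisfiable constraint")


def is_monophyletic(tree: PhyloTree, group: TaxonSet,
                    outgroup: TaxonSet) -> bool:
    """Does ``group`` form a clade on the outgroup-rooted tree?

    Equivalently: the group is one side of a split with the outgroup
    wholly on the other side.  Single-member groups and the full
    ingroup are trivially monophyletic.
    """
    gmask = tree.taxon_mask(group.members)
    omask = tree.taxon_mask(outgroup.members)
    if gmask & omask:
        raise ValueError(f"group {group.name!r} overlaps the outgroup")
    full = (1 << tree.n_taxa) - 1
    if bin(gmask).count("1") <= 1 or bin(full ^ gmask).count("1") <= 1:
        return True
    return tree.has_split(gmask)


def constrained_search(matrix: CharacterMatrix,
                       spec: ConstraintSpec,
                       config: SearchConfig | None = None) -> SearchResult:
    """TBR search over constraint-satisfying trees only.

    Wagner starts are built group-first so each start already satisfies
    the constraints; rearrangements that break a group are skipped.
    An empty spec reduces to the unconstrained search.
    """
    return tbr_search(matrix, config, require=spec.groups)


def step_difference(constrained: SearchResult,
                    unconstrained: SearchResult) -> int:
    """Extra steps demanded by the constraint; never negative."""
    diff = constrained.best_length - unconstrained.best_length
    if diff < 0:
        raise RuntimeError(
            "constrained search found a shorter tree than the "
            "unconstrained one: the unconstrained search must be broken")
    return diff
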