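"""Strict consensus and Bremer (decay) support."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .matrix import CharacterMatrix, TaxonSet
from .search import SearchConfig, SearchResult, tbr_search
from .tree import PhyloTree, normalize_split, popcount

__all__ = ["SplitSet", "strict_consensus", "BremerTable", "bremer_support"]


@dataclass(frozen=True)
class SplitSet:
    """The nontrivial bipartitions of one tree (normalised bitmasks)."""

    splits: frozenset[int]
    n_leaves: int

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "SplitSet":
        return cls(tree.splits, tree.n_taxa)

    def __and__(self, other: "SplitSet") -> "SplitSet":
        if self.n_leaves != other.n_leaves:
            raise ValueError("split sets over different leaf counts")
        return SplitSet(self.splits & other.splits, self.n_leaves)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits common to all inputs."""
    if not trees:
        raise ValueError("need at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees must share one leaf set")
    common = frozenset.intersection(*(t.splits for t in trees))
    return PhyloTree.from_splits(common, taxa)


@dataclass
class BremerTable:
    """Decay values per clade of a reference (consensus) tree.

    ``decay[mask]`` is the extra length of the shortest tree in which
    the clade does not appear (converse-constraint search result minus
    the unconstrained optimum).  ``converged[mask]`` is False when the
    per-clade search is suspected not to have found that shortest tree
    (heuristic caveat: decay values are upper bounds).
    """

    reference: PhyloTree
    best_length: int
    decay: dict[int, int] = field(default_factory=dict)
    converged: dict[int, bool] = field(default_factory=dict)

    def decay_for(self, labels: Iterable[str]) -> int:
        """Decay value of the clade given by taxon labels (either side
        of the split may be named)."""
        mask = normalize_split(self.reference.taxon_mask(labels),
                               self.reference.n_taxa)
        return self.decay[mask]

    def clade_taxa(self, mask: int) -> tuple[str, ...]:
        return tuple(t for i, t in enumerate(self.reference.taxa)
                     if mask >> i & 1)

    def annotated_newick(self, root_on: str | None = None) -> str:
        return self.reference.to_newick(root_on=root_on, labels={
            m: str(d) for m, d in self.decay.items()})

    def to_rows(self) -> list[dict]:
        rows = []
        for mask in sorted(self.decay, key=popcount):
            rows.append({"clade": ",".join(self.clade_taxa(mask)),
                         "decay": self.decay[mask],
                         "converged": self.converged.get(mask, True)})
        return rows


def bremer_support(matrix: CharacterMatrix,
                   consensus: PhyloTree,
                   config: SearchConfig | None = None,
                   best_length: int | None = None,
                   splits: Iterable[int] | None = None) -> BremerTable:
    """Bremer decay values by per-clade converse-constraint searches.

    For every split of ``consensus`` (or the given subset), a TBR
    search is run over trees in which that taxon set does *not* form a
    clade; the decay value is the length excess of the best such tree.
    Pooling suboptimal trees under a hold limit would understate decay,
    hence one search per clade.
    """
    config = config or SearchConfig(replicates=20)
    n = consensus.n_taxa
    if best_length is None:
        best_length = tbr_search(matrix, config).best_length
    table = BremerTable(consensus, best_length)
    for mask in sorted(splits if splits is not None else consensus.splits,
                       key=popcount):
        mask = normalize_split(int(mask), n)
        group = TaxonSet(f"clade_{mask:x}",
                         frozenset(table.clade_taxa(mask)))
        res = tbr_search(matrix, config, forbid=[group])
        table.decay[mask] = res.best_length - best_length
        # convergence heuristic: the converse search must have found
        # trees at least as short as the unconstrained optimum allows
        table.converged[mask] = res.best_length >= best_length
    return table
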