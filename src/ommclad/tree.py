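"""Unrooted phylogenetic trees over a fixed taxon set.

A :class:`PhyloTree` is an unrooted tree whose identity is its set of
nontrivial leaf bipartitions (splits).  Splits are stored as integer
bitmasks over the taxon indices, normalised to the side that does not
contain taxon 0, which makes topological comparison, deduplication and
consensus computation cheap set arithmetic.  Binary trees additionally
carry an adjacency-array form used by the search kernels.

Node layout for binary trees with ``n`` leaves: nodes ``0..n-1`` are the
leaves (in taxon order), nodes ``n..2n-3`` are internal; ``adj`` is an
``(2n-2, 3)`` int32 array of neighbour ids, ``-1``-padded for leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "popcount", "normalize_split"]


def popcount(mask: int) -> int:
    return bin(mask).count("1")


def normalize_split(mask: int, n: int) -> int:
    """Return the side of the bipartition that excludes taxon 0."""
    full = (1 << n) - 1
    return (full ^ mask) if (mask & 1) else mask


def _splits_from_adjacency(adj: np.ndarray, n: int) -> frozenset[int]:
    """Nontrivial splits of a binary unrooted tree, normalised."""
    m = adj.shape[0]
    below = [0] * m
    parent = [-1] * m
    order: list[int] = []
    stack = [0]
    parent[0] = -2
    while stack:
        v = stack.pop()
        order.append(v)
        for k in range(3):
            u = int(adj[v, k])
            if u >= 0 and u != parent[v]:
                parent[u] = v
                stack.append(u)
    for v in reversed(order):
        if v < n:
            below[v] = 1 << v
        else:
            acc = 0
            for k in range(3):
                u = int(adj[v, k])
                if u >= 0 and u != parent[v]:
                    acc |= below[u]
            below[v] = acc
    splits = set()
    for v in order[1:]:
        side = below[v]
        c = popcount(side)
        if 2 <= c <= n - 2:
            splits.add(normalize_split(side, n))
    return frozenset(splits)


def _check_compatible(splits: Iterable[int], n: int) -> None:
    full = (1 << n) - 1
    ss = sorted(splits)
    for i, a in enumerate(ss):
        for b in ss[i + 1:]:
            if a & b and (a | b) != a and (a | b) != b and (a | b) != full:
                raise ValueError(f"incompatible splits {a:#x} and {b:#x}")


@dataclass(frozen=True)
class PhyloTree:
    """An unrooted tree, possibly with soft polytomies.

    Parameters
    ----------
    taxa:
        Ordered taxon labels; taxon ``i`` is leaf/bit ``i``.
    splits:
        Nontrivial splits as bitmasks normalised away from taxon 0.
    adj:
        Optional adjacency array; present only for binary trees.
    """

    taxa: tuple[str, ...]
    splits: frozenset[int]
    adj: np.ndarray | None = field(default=None, compare=False, repr=False)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_adjacency(cls, adj: np.ndarray, taxa: Sequence[str]) -> "PhyloTree":
        n = len(taxa)
        return cls(tuple(taxa), _splits_from_adjacency(adj, n),
                   np.ascontiguousarray(adj, dtype=np.int32))

    @classmethod
    def from_splits(cls, splits: Iterable[int], taxa: Sequence[str]) -> "PhyloTree":
        taxa = tuple(taxa)
        n = len(taxa)
        norm = frozenset(normalize_split(int(s), n) for s in splits
                         if 2 <= popcount(normalize_split(int(s), n)) <= n - 2)
        _check_compatible(norm, n)
        tree = cls(taxa, norm)
        if tree.is_binary():
            tree = cls(taxa, norm, tree._adjacency_from_splits())
        return tree

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        labels = sorted(l.taxon.label for l in dtree.leaf_node_iter())
        if taxa is None:
            taxa = labels
        elif sorted(taxa) != labels:
            raise ValueError("newick leaf set does not match taxa")
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        splits = set()

        def mask_below(node) -> int:
            if node.is_leaf():
                return 1 << index[node.taxon.label]
            acc = 0
            for ch in node.child_nodes():
                acc |= mask_below(ch)
            c = popcount(acc)
            if 2 <= c <= n - 2:
                splits.add(normalize_split(acc, n))
            return acc

        mask_below(dtree.seed_node)
        return cls.from_splits(splits, taxa)

    # -- basic queries ------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def is_binary(self) -> bool:
        return len(self.splits) == max(self.n_taxa - 3, 0)

    def has_split(self, mask: int) -> bool:
        return normalize_split(mask, self.n_taxa) in self.splits

    def rf_distance(self, other: "PhyloTree") -> int:
        if self.taxa != other.taxa:
            raise ValueError("trees are over different taxon sets")
        return len(self.splits ^ other.splits)

    def taxon_mask(self, labels: Iterable[str]) -> int:
        index = {t: i for i, t in enumerate(self.taxa)}
        mask = 0
        for lab in labels:
            if lab not in index:
                raise KeyError(f"unknown taxon {lab!r}")
            mask |= 1 << index[lab]
        return mask

    # -- adjacency ----------------------------------------------------

    def adjacency(self) -> np.ndarray:
        if self.adj is None:
            raise ValueError("tree is not binary; no adjacency form")
        return self.adj

    def _adjacency_from_splits(self) -> np.ndarray:
        """Build the adjacency array of a fully resolved tree."""
        n = self.n_taxa
        if n < 3:
            raise ValueError("need at least 3 taxa")
        m = 2 * n - 2
        adj = np.full((m, 3), -1, dtype=np.int32)
        degree = np.zeros(m, dtype=np.int32)

        def connect(a: int, b: int) -> None:
            adj[a, degree[a]] = b
            adj[b, degree[b]] = a
            degree[a] += 1
            degree[b] += 1

        # Treat the tree as rooted at taxon 0: every split (normalised away
        # from taxon 0) is a clade.  Nest clades by containment.
        clades = sorted(self.splits, key=popcount)
        full_ingroup = ((1 << n) - 1) ^ 1
        items = [(1 << i, i) for i in range(1, n)]  # (mask, node id)
        next_node = n
        for cl in clades + [full_ingroup]:
            members = [it for it in items if it[0] & cl]
            rest = [it for it in items if not (it[0] & cl)]
            if len(members) < 2:
                raise ValueError("splits are not mutually compatible")
            # chain members into a binary clade (order fixed by mask)
            members.sort(key=lambda it: it[0])
            cur_mask, cur_node = members[0]
            for mmask, mnode in members[1:]:
                connect(cur_node, next_node)
                connect(mnode, next_node)
                cur_mask, cur_node = cur_mask | mmask, next_node
                next_node += 1
            items = rest + [(cur_mask, cur_node)]
        assert len(items) == 1
        connect(0, items[0][1])
        assert next_node == m
        return adj

    # -- newick -------------------------------------------------------

    def to_newick(self, root_on: str | None = None,
                  labels: dict[int, str] | None = None) -> str:
        """Serialise to newick, rooted for display.

        Parameters
        ----------
        root_on:
            Taxon label used as the basal-most leaf (display rooting);
            defaults to the first taxon.
        labels:
            Optional internal-node labels keyed by normalised split mask
            (used to annotate clades, e.g. with Bremer values).
        """
        n = self.n_taxa
        root_idx = 0 if root_on is None else self.taxa.index(root_on)
        full = (1 << n) - 1

        def orient(mask: int) -> int:
            # side of the split away from the display root
            return (full ^ mask) if (mask & (1 << root_idx)) else mask

        clades = sorted((orient(s) for s in self.splits), key=popcount)
        ingroup = full ^ (1 << root_idx)
        items: list[tuple[int, str]] = [(1 << i, self.taxa[i])
                                        for i in range(n) if i != root_idx]
        for cl in clades + [ingroup]:
            members = [it for it in items if it[0] & cl]
            rest = [it for it in items if not (it[0] & cl)]
            mask = 0
            for mm, _ in members:
                mask |= mm
            lab = ""
            if labels:
                key = normalize_split(mask, n)
                if key in labels:
                    lab = str(labels[key])
            text = "(" + ",".join(t for _, t in members) + ")" + lab
            items = rest + [(mask, text)]
        return f"({self.taxa[root_idx]},{items[0][1]});"


def write_newick(trees: Iterable[PhyloTree], path, root_on: str | None = None) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(root_on=root_on) + "\n")


def read_newick(path, taxa: Sequence[str] | None = None) -> list[PhyloTree]:
    with open(path) as fh:
        text = fh.read()
    out = []
    for line in text.strip().splitlines():
        line = line.strip()
        if line:
            out.append(PhyloTree.from_newick(line, taxa))
    return out
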