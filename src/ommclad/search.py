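"""Heuristic and exact searches for minimum-length trees.

The heuristic follows the classic two-phase strategy: many random
addition-sequence (Wagner) starts, each taken to a local optimum by
tree-bisection-reconnection (TBR) branch swapping, then a final round
of TBR over the retained optimal trees that also harvests every
equal-length neighbour ("TBR + TBR").  Retained trees are deduplicated
by their unrooted split sets; zero-length internal branches are
collapsed under a configurable rule before most-parsimonious-tree
counts are reported, because those counts depend on the rule.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import (apply_tbr, collapsed_splits, constraints_ok,
                       fitch_total, tbr_scan, wagner_build, _insert_leaf)
from .matrix import CharacterMatrix, TaxonSet
from .tree import PhyloTree, normalize_split

__all__ = ["SearchConfig", "SearchResult", "wagner_addition", "tbr_search",
           "branch_and_bound", "collapse"]

_RULES = {"min_zero": 0, "max_zero": 1, "none": 2}
_EMPTY_MASKS = np.empty(0, dtype=np.int64)
_EMPTY_SIGNS = np.empty(0, dtype=np.int8)
_EMPTY_MOVES = np.empty((0, 6), dtype=np.int32)
_MOVE_BUFFER = 1 << 16


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the heuristic search.

    ``hold`` caps the number of retained optimal trees; ``replicates``
    is the number of random-addition starts; ``collapse_rule`` decides
    when an internal branch of zero length is contracted (``min_zero``:
    if its length is zero in some most parsimonious reconstruction,
    ``max_zero``: only if it is zero in all of them, ``none``: never).
    """

    hold: int = 10000
    replicates: int = 1000
    swapper: str = "tbr"
    seed: int = 0
    collapse_rule: str = "min_zero"

    def __post_init__(self):
        if self.hold < 1 or self.replicates < 1:
            raise ValueError("hold and replicates must be >= 1")
        if self.collapse_rule not in _RULES:
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")
        if self.swapper != "tbr":
            raise ValueError("only TBR swapping is implemented")


@dataclass
class SearchResult:
    """Optimal trees found by a search, with provenance."""

    best_length: int
    trees: list[PhyloTree]          # after collapsing, deduplicated
    binary_trees: list[PhyloTree]   # as retained by the search
    config: SearchConfig
    replicate_log: list[tuple[int, int]] = field(default_factory=list)
    hold_hit: bool = False
    move_buffer_hit: bool = False

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _group_arrays(matrix: CharacterMatrix,
                  require: Sequence[TaxonSet] = (),
                  forbid: Sequence[TaxonSet] = ()):
    masks, signs = [], []
    for grp, sign in [(require, 1), (forbid, -1)]:
        for g in grp:
            mask = 0
            for t in g.members:
                mask |= 1 << matrix.taxon_index(t)
            if bin(mask).count("1") < 2:
                raise ValueError(f"group {g.name!r} needs >= 2 taxa")
            masks.append(mask)
            signs.append(sign)
    if not masks:
        return _EMPTY_MASKS, _EMPTY_SIGNS
    return (np.array(masks, dtype=np.int64), np.array(signs, dtype=np.int8))


def _canonical_key(adj: np.ndarray, n: int) -> frozenset[int]:
    return PhyloTree.from_adjacency(adj, [str(i) for i in range(n)]).splits


def _descend(adj, states, n, length, masks, signs):
    """TBR to a local optimum (steepest descent)."""
    while True:
        best, u, v, a1, b1, a2, b2, _ = tbr_scan(
            adj, states, n, 0, length, masks, signs, _EMPTY_MOVES)
        if u < 0:
            return adj, length
        out = np.empty_like(adj)
        apply_tbr(adj, out, n, u, v, a1, b1, a2, b2)
        adj, length = out, best


def _satisfies(adj, n, masks, signs) -> bool:
    if masks.shape[0] == 0:
        return True
    full = (1 << n) - 1
    return bool(constraints_ok(adj, 0, n, full, masks, signs))


def _break_forbidden(adj, n, states, masks, signs, rng):
    """Randomly move leaves until no forbidden group forms a clade."""
    for _ in range(200):
        if _satisfies(adj, n, masks, signs):
            return adj
        # move a random member of some violated forbidden group next to
        # a random leaf outside the group
        full = (1 << n) - 1
        for g in range(masks.shape[0]):
            if signs[g] >= 0:
                continue
            gm = int(masks[g])
            members = [i for i in range(n) if gm >> i & 1]
            outsiders = [i for i in range(n) if not gm >> i & 1]
            leaf = int(rng.choice(members))
            target = int(rng.choice(outsiders))
            pv = int(adj[leaf, 0])
            tj = int(adj[target, 0])
            if pv == tj:
                continue
            out = np.empty_like(adj)
            apply_tbr(adj, out, n, leaf, pv, leaf, leaf, target, tj)
            adj = out
    raise RuntimeError("could not construct a start tree violating the "
                       "forbidden clade")


def wagner_addition(matrix: CharacterMatrix,
                    order: Sequence[int] | None = None,
                    seed: int = 0,
                    require: Sequence[TaxonSet] = ()) -> PhyloTree:
    """Greedy stepwise-addition starting tree.

    Taxa are added in ``order`` (default: matrix order), each on the
    edge that minimises the resulting length; ties are broken by a
    seeded uniform choice.  Groups in ``require`` are kept monophyletic
    at every stage.
    """
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if order is None:
        order = np.arange(n, dtype=np.int32)
    else:
        order = np.asarray(order, dtype=np.int32)
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of taxon indices")
    masks, signs = _group_arrays(matrix, require)
    adj = wagner_build(matrix.state_masks(), n, order, seed, masks, signs)
    return PhyloTree.from_adjacency(adj, matrix.taxa)


def collapse(tree: PhyloTree, matrix: CharacterMatrix,
             rule: str = "min_zero") -> PhyloTree:
    """Contract zero-length internal branches of a binary tree."""
    if rule not in _RULES:
        raise ValueError(f"unknown collapse rule {rule!r}")
    if not tree.is_binary():
        raise ValueError("collapse expects a binary tree")
    if list(tree.taxa) != matrix.taxa:
        matrix = matrix.subset_taxa(list(tree.taxa))
    n = matrix.n_taxa
    nstates = np.array([c.n_states for c in matrix.characters],
                       dtype=np.int64)
    out = np.empty(2 * n, dtype=np.int64)
    cnt = collapsed_splits(tree.adjacency(), matrix.state_masks(), n,
                           nstates, _RULES[rule], out)
    return PhyloTree.from_splits([int(x) for x in out[:cnt]], tree.taxa)


def tbr_search(matrix: CharacterMatrix,
               config: SearchConfig | None = None,
               require: Sequence[TaxonSet] = (),
               forbid: Sequence[TaxonSet] = ()) -> SearchResult:
    """Random-addition TBR search for minimum-length trees.

    ``require``/``forbid`` restrict the search to trees in which the
    given taxon sets do / do not form clades; the start trees are built
    accordingly and every accepted rearrangement is checked.
    """
    config = config or SearchConfig()
    n = matrix.n_taxa
    if n < 4:
        raise ValueError("heuristic search needs >= 4 taxa")
    states = matrix.state_masks()
    masks, signs = _group_arrays(matrix, require, forbid)
    has_forbid = bool(len(forbid))
    rng = np.random.default_rng(config.seed)

    best: int | None = None
    pool: dict[frozenset, np.ndarray] = {}
    log: list[tuple[int, int]] = []
    hold_hit = False

    for rep in range(config.replicates):
        order = np.asarray(rng.permutation(n), dtype=np.int32)
        wseed = int(rng.integers(1 << 31))
        adj = wagner_build(states, n, order, wseed, masks, signs)
        if has_forbid:
            adj = _break_forbidden(adj, n, states, masks, signs, rng)
        length = int(fitch_total(adj, states, 0))
        adj, length = _descend(adj, states, n, length, masks, signs)
        log.append((rep, length))
        if best is None or length < best:
            best = length
            pool.clear()
        if length == best:
            key = _canonical_key(adj, n)
            if key not in pool:
                if len(pool) < config.hold:
                    pool[key] = adj
                else:
                    hold_hit = True

    # final pass: swap the retained trees, harvesting equal-length
    # neighbours until closure
    moves = np.empty((_MOVE_BUFFER, 6), dtype=np.int32)
    queue = deque(pool.values())
    buffer_hit = False
    while queue:
        adj = queue.popleft()
        res = tbr_scan(adj, states, n, 1, best, masks, signs, moves)
        nout = res[7]
        if nout > _MOVE_BUFFER:
            buffer_hit = True
            nout = _MOVE_BUFFER
        for i in range(nout):
            if len(pool) >= config.hold:
                hold_hit = True
                break
            u, v, a1, b1, a2, b2 = (int(x) for x in moves[i])
            out = np.empty_like(adj)
            apply_tbr(adj, out, n, u, v, a1, b1, a2, b2)
            key = _canonical_key(out, n)
            if key not in pool:
                pool[key] = out
                queue.append(out)
        if hold_hit:
            break

    binary_trees = [PhyloTree.from_adjacency(a, matrix.taxa)
                    for a in pool.values()]
    # safety: every retained tree rescored from scratch
    for a in pool.values():
        assert int(fitch_total(a, states, 0)) == best
    trees = _collapsed_unique(pool.values(), matrix, config.collapse_rule)
    return SearchResult(int(best), trees, binary_trees, config, log,
                        hold_hit, buffer_hit)


def _collapsed_unique(adjs, matrix: CharacterMatrix, rule: str
                      ) -> list[PhyloTree]:
    n = matrix.n_taxa
    nstates = np.array([c.n_states for c in matrix.characters],
                       dtype=np.int64)
    states = matrix.state_masks()
    out = np.empty(2 * n, dtype=np.int64)
    seen: dict[frozenset, PhyloTree] = {}
    for adj in adjs:
        cnt = collapsed_splits(adj, states, n, nstates, _RULES[rule], out)
        key = frozenset(normalize_split(int(x), n) for x in out[:cnt])
        if key not in seen:
            seen[key] = PhyloTree.from_splits(key, matrix.taxa)
    return list(seen.values())


def recount_mpts(result: SearchResult, matrix: CharacterMatrix,
                 rule: str) -> int:
    """Number of distinct optimal trees under another collapse rule."""
    adjs = [t.adjacency() for t in result.binary_trees]
    return len(_collapsed_unique(adjs, matrix, rule))


def branch_and_bound(matrix: CharacterMatrix,
                     max_taxa: int = 12,
                     collapse_rule: str = "min_zero") -> SearchResult:
    """Exact search: provably all minimum-length binary trees.

    Exhaustive stepwise enumeration with branch-and-bound pruning
    (adding a taxon can never decrease tree length).  Refuses matrices
    with more than ``max_taxa`` taxa.
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(f"branch_and_bound limited to {max_taxa} taxa, "
                         f"got {n}")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    states = matrix.state_masks()
    config = SearchConfig(replicates=1, seed=0, collapse_rule=collapse_rule)
    if n == 3:
        adj = wagner_build(states, n, np.arange(n, dtype=np.int32), 0,
                           _EMPTY_MASKS, _EMPTY_SIGNS)
        tree = PhyloTree.from_adjacency(adj, matrix.taxa)
        ln = int(fitch_total(adj, states, 0))
        return SearchResult(ln, _collapsed_unique([adj], matrix,
                                                  collapse_rule),
                            [tree], config)

    # initial upper bound from a quick heuristic pass
    adj0 = wagner_build(states, n, np.arange(n, dtype=np.int32), 0,
                        _EMPTY_MASKS, _EMPTY_SIGNS)
    adj0, ub = _descend(adj0, states, n, int(fitch_total(adj0, states, 0)),
                        _EMPTY_MASKS, _EMPTY_SIGNS)

    best = [int(ub)]
    found: dict[frozenset, np.ndarray] = {}
    M = 2 * n - 2

    def edges_of(adj, cnt_nodes):
        seen = []
        for a in range(M):
            for k in range(3):
                b = int(adj[a, k])
                if b > a:
                    seen.append((a, b))
        return seen

    def recurse(adj, k, next_int, length):
        if k == n:
            if length < best[0]:
                best[0] = length
                found.clear()
            if length == best[0]:
                key = _canonical_key(adj, n)
                if key not in found:
                    found[key] = adj.copy()
            return
        t = k  # taxa added in matrix order
        for (a, b) in edges_of(adj, None):
            out = adj.copy()
            _insert_leaf(out, t, next_int, a, b)
            ln = int(fitch_total(out, states, 0))
            if ln <= best[0]:
                recurse(out, k + 1, next_int + 1, ln)

    start = np.full((M, 3), -1, dtype=np.int32)
    hub = n
    start[hub, 0], start[hub, 1], start[hub, 2] = 0, 1, 2
    start[0, 0] = start[1, 0] = start[2, 0] = hub
    recurse(start, 3, n + 1, int(fitch_total(start, states, 0)))

    binary_trees = [PhyloTree.from_adjacency(a, matrix.taxa)
                    for a in found.values()]
    trees = _collapsed_unique(found.values(), matrix, collapse_rule)
    return SearchResult(best[0], trees, binary_trees, config)
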