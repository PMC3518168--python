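"""Synthetic morphological matrices with known generating trees.

Characters evolve independently along a uniformly sampled unrooted
binary topology under a symmetric k-state (Mk) model, then cells are
masked as missing/inapplicable at configurable rates.  The default
shape mirrors the packaged beetle matrix: 28 taxa, 28 characters, one
3-state character, about 10% missing data, and roughly two expected
changes per character across the tree (comparable homoplasy to the
real data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import (CharacterDefinition, CharacterMatrix, MISSING,
                     INAPPLICABLE)
from .tree import PhyloTree

__all__ = ["SimConfig", "simulate_tree", "simulate_matrix"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``expected_changes`` is the expected number of substitutions per
    character summed over the whole tree (branch lengths are equal
    across edges); lowering it towards ~0.05 gives effectively
    homoplasy-free matrices, raising it increases homoplasy.
    """

    n_taxa: int = 28
    n_characters: int = 28
    three_state: tuple[int, ...] = (4,)
    expected_changes: float = 2.0
    missing_fraction: float = 0.10
    inapplicable_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for f in (self.missing_fraction, self.inapplicable_fraction):
            if not 0.0 <= f < 1.0:
                raise ValueError("mask fractions must be in [0, 1)")
        if self.expected_changes < 0:
            raise ValueError("expected_changes must be >= 0")


def simulate_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Uniformly sampled unrooted binary topology.

    Random sequential addition: each taxon is attached to an edge drawn
    uniformly at random, which yields the uniform distribution over
    labelled unrooted binary topologies.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    n = n_taxa
    M = 2 * n - 2
    adj = np.full((M, 3), -1, dtype=np.int32)
    hub = n
    adj[hub, :] = (0, 1, 2)
    adj[0, 0] = adj[1, 0] = adj[2, 0] = hub
    edges = [(0, hub), (1, hub), (2, hub)]
    next_int = n + 1
    for t in range(3, n):
        a, b = edges[rng.integers(len(edges))]
        j = next_int
        next_int += 1
        for k in range(3):
            if adj[a, k] == b:
                adj[a, k] = j
            if adj[b, k] == a:
                adj[b, k] = j
        adj[j, :] = (a, b, t)
        adj[t, 0] = j
        edges.remove((a, b))
        edges += [(a, j), (b, j), (t, j)]
    return PhyloTree.from_adjacency(adj, taxa)


def _p_change(branch_length: float, k: int) -> float:
    """Probability a symmetric k-state chain ends in a different state."""
    return (k - 1) / k * (1.0 - math.exp(-k * branch_length / (k - 1)))


def simulate_matrix(tree: PhyloTree, config: SimConfig) -> CharacterMatrix:
    """Evolve a matrix on ``tree`` under the symmetric Mk model."""
    if not tree.is_binary():
        raise ValueError("simulation requires a binary tree")
    n = tree.n_taxa
    if n != config.n_taxa:
        raise ValueError("tree size does not match config.n_taxa")
    rng = np.random.default_rng(config.seed)
    adj = tree.adjacency()
    M = adj.shape[0]
    n_edges = 2 * n - 3
    t_edge = config.expected_changes / n_edges

    # rooted traversal from leaf 0
    parent = np.full(M, -1, dtype=np.int64)
    parent[0] = -2
    order = [0]
    stack = [0]
    while stack:
        v = stack.pop()
        for k in range(3):
            u = int(adj[v, k])
            if u >= 0 and parent[u] == -1:
                parent[u] = v
                order.append(u)
                stack.append(u)

    cells = np.empty((n, config.n_characters), dtype=np.int8)
    chars = []
    for j in range(config.n_characters):
        k = 3 if j in config.three_state else 2
        chars.append(CharacterDefinition(j, f"sim_{j}", k))
        p = _p_change(t_edge, k)
        state = np.empty(M, dtype=np.int8)
        state[0] = rng.integers(k)
        for v in order[1:]:
            s = state[parent[v]]
            if rng.random() < p:
                s = (s + 1 + rng.integers(k - 1)) % k
            state[v] = s
        cells[:, j] = state[:n]

    u = rng.random(cells.shape)
    cells[u < config.inapplicable_fraction] = INAPPLICABLE
    mask_lo = config.inapplicable_fraction
    cells[(u >= mask_lo)
          & (u < mask_lo + config.missing_fraction)] = MISSING
    return CharacterMatrix(list(tree.taxa), chars, cells)
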