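"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

import ommclad as oc


@pytest.fixture(scope="session")
def beetle_matrix():
    return oc.ommatidae_matrix()


def all_topologies(n):
    """Every unrooted binary topology over taxa 0..n-1 (enumeration
    oracle, independent of the search code): stepwise addition of taxon
    k on each edge of each smaller topology."""
    # a tree is an edge list over leaf ids < n and internal ids >= 100
    trees = [[(0, 100), (1, 100), (2, 100)]]
    for k in range(3, n):
        new = []
        for edges in trees:
            for i, (a, b) in enumerate(edges):
                j = 100 + (k - 2) * 100  # unique internal id per level
                rest = edges[:i] + edges[i + 1:]
                new.append(rest + [(a, j), (b, j), (k, j)])
        trees = new
    return trees


def edges_to_splits(edges, n):
    """Nontrivial splits of an edge-list tree (oracle)."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b in edges:
        # leaves on a's side without crossing (a, b)
        seen = {a}
        stack = [a]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in seen and not (v == a and u == b):
                    seen.add(u)
                    stack.append(u)
        mask = 0
        for v in seen:
            if v < n:
                mask |= 1 << v
        c = bin(mask).count("1")
        if 2 <= c <= n - 2:
            full = (1 << n) - 1
            splits.add((full ^ mask) if mask & 1 else mask)
    return frozenset(splits)


def brute_force_length(edges, matrix):
    """Minimum changes by exhaustive enumeration of internal (and
    unobserved leaf) state assignments.  Exponential: small trees only."""
    n = matrix.n_taxa
    nodes = sorted({v for e in edges for v in e})
    total = 0
    for j, ch in enumerate(matrix.characters):
        k = ch.n_states
        col = matrix.column(j)
        free = [v for v in nodes if v >= n or col[v] < 0]
        fixed = {v: int(col[v]) for v in nodes if v < n and col[v] >= 0}
        best = 10 ** 9
        for assign in itertools.product(range(k), repeat=len(free)):
            lab = dict(fixed)
            lab.update(zip(free, assign))
            changes = sum(1 for a, b in edges if lab[a] != lab[b])
            best = min(best, changes)
        total += best
    return total


def tree_from_edges(edges, taxa):
    return oc.PhyloTree.from_splits(edges_to_splits(edges, len(taxa)), taxa)


def random_small_matrix(seed, n_taxa=None, n_chars=5):
    """A random small matrix with some missing/inapplicable cells."""
    rng = np.random.default_rng(seed)
    if n_taxa is None:
        n_taxa = int(rng.integers(5, 9))
    tree = oc.simulate_tree(n_taxa, seed=seed)
    config = oc.SimConfig(n_taxa=n_taxa, n_characters=n_chars,
                          expected_changes=float(rng.uniform(1.0, 4.0)),
                          missing_fraction=0.1, inapplicable_fraction=0.03,
                          seed=seed, three_state=(0,))
    return oc.simulate_matrix(tree, config), tree
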