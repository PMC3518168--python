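"""Strict consensus and Bremer support."""

import numpy as np
import pytest

import ommclad as oc
from ommclad.matrix import CharacterDefinition, CharacterMatrix

from conftest import all_topologies, brute_force_length, edges_to_splits


def test_consensus_of_identical_trees_is_that_tree():
    t = oc.simulate_tree(8, seed=1)
    assert oc.strict_consensus([t, t, t]).splits == t.splits


def test_consensus_of_conflicting_trees_is_star():
    a = oc.PhyloTree.from_newick("((A,B),(C,D),(E,F));",
                                 list("ABCDEF"))
    b = oc.PhyloTree.from_newick("((A,F),(C,E),(B,D));",
                                 list("ABCDEF"))
    assert len(oc.strict_consensus([a, b]).splits) == 0


@pytest.mark.parametrize("seed", range(5))
def test_consensus_equals_split_intersection(seed):
    rng = np.random.default_rng(seed)
    trees = [oc.simulate_tree(9, seed=int(rng.integers(1000)))
             for _ in range(4)]
    cons = oc.strict_consensus(trees)
    assert cons.splits == frozenset.intersection(*(t.splits for t in trees))


def test_consensus_is_order_invariant():
    trees = [oc.simulate_tree(7, seed=s) for s in range(4)]
    a = oc.strict_consensus(trees)
    b = oc.strict_consensus(trees[::-1])
    assert a.splits == b.splits


def test_consensus_rejects_mismatched_leaf_sets():
    a = oc.simulate_tree(6, seed=0)
    b = oc.simulate_tree(7, seed=0)
    with pytest.raises(ValueError):
        oc.strict_consensus([a, b])


def _decay_matrix():
    """Six taxa; {A,B,C} supported by three uncontradicted characters,
    {A,B} and {D,E} each by one."""
    rows = {
        "A": [1, 1, 1, 1, 0],
        "B": [1, 1, 1, 1, 0],
        "C": [1, 1, 1, 0, 0],
        "D": [0, 0, 0, 0, 1],
        "E": [0, 0, 0, 0, 1],
        "F": [0, 0, 0, 0, 0],
    }
    taxa = list(rows)
    chars = [CharacterDefinition(j, n_states=2) for j in range(5)]
    return CharacterMatrix(taxa, chars,
                           np.array([rows[t] for t in taxa], dtype=np.int8))


def test_bremer_decay_three_uncontradicted_characters():
    """The clade backed by three clean characters decays at three extra
    steps; verified against exhaustive search over all 105 topologies."""
    m = _decay_matrix()
    res = oc.branch_and_bound(m)
    cons = oc.strict_consensus(res.binary_trees)
    from ommclad.tree import normalize_split
    n = m.n_taxa
    abc = normalize_split(cons.taxon_mask(["A", "B", "C"]), n)
    # exhaustive oracle: shortest topology lacking the {A,B,C} split
    best_without = min(
        brute_force_length(e, m) for e in all_topologies(n)
        if abc not in edges_to_splits(e, n))
    table = oc.bremer_support(m, cons, oc.SearchConfig(replicates=10, seed=0),
                              best_length=res.best_length, splits=[abc])
    assert table.decay_for(["A", "B", "C"]) == best_without - res.best_length == 3


def test_bremer_decay_zero_for_clade_absent_from_some_mpt():
    """A clade present in only part of the MPT set has decay 0."""
    rows = {"A": [1, 1, 1, 0], "B": [1, 1, 1, 0], "C": [1, 1, 1, 0],
            "D": [0, 0, 0, 1], "E": [0, 0, 0, 1], "F": [0, 0, 0, 0]}
    taxa = list(rows)
    m = CharacterMatrix(taxa,
                        [CharacterDefinition(j, n_states=2) for j in range(4)],
                        np.array([rows[t] for t in taxa], dtype=np.int8))
    res = oc.branch_and_bound(m)
    # the {A,B,C} polytomy resolves three ways: {A,B} is in some MPTs
    # but not all, so it decays at zero extra steps
    some = set().union(*(t.splits for t in res.binary_trees))
    shared = frozenset.intersection(*(t.splits for t in res.binary_trees))
    mask = res.binary_trees[0].taxon_mask(["A", "B"])
    partial = {s for s in some - shared
               if bin(s).count("1") == 2 and s & mask}
    assert partial, "expected an ambiguous two-taxon clade"
    mask = next(iter(partial))
    table = oc.bremer_support(m, res.binary_trees[0],
                              oc.SearchConfig(replicates=10, seed=0),
                              best_length=res.best_length, splits=[mask])
    assert list(table.decay.values()) == [0]


def test_bremer_decay_at_least_one_for_complete_consensus_splits():
    """Splits shared by the complete MPT set (exact search) decay by
    at least one step."""
    matrix = _decay_matrix()
    res = oc.branch_and_bound(matrix)
    cons = oc.strict_consensus(res.binary_trees)
    table = oc.bremer_support(matrix, cons,
                              oc.SearchConfig(replicates=10, seed=1),
                              best_length=res.best_length)
    assert all(d >= 1 for d in table.decay.values())


def test_bremer_monotone_in_search_budget(beetle_matrix):
    """Decay estimates never decrease when the converse-constraint
    search budget grows (more replicates can only find shorter
    counter-trees)."""
    res = oc.tbr_search(beetle_matrix, oc.SearchConfig(replicates=20, seed=2))
    cons = oc.strict_consensus(res.binary_trees)
    mask = max(cons.splits, key=lambda s: bin(s).count("1"))
    small = oc.bremer_support(beetle_matrix, cons,
                              oc.SearchConfig(replicates=2, seed=5),
                              best_length=res.best_length, splits=[mask])
    large = oc.bremer_support(beetle_matrix, cons,
                              oc.SearchConfig(replicates=10, seed=5),
                              best_length=res.best_length, splits=[mask])
    assert list(large.decay.values())[0] <= list(small.decay.values())[0]
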