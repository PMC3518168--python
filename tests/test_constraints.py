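"""Monophyly checks, constrained searches, step differences."""

import numpy as np
import pytest

import ommclad as oc

from conftest import random_small_matrix


def _taxonset(tree, labels, name="g"):
    return oc.TaxonSet(name, frozenset(labels))


def test_cherry_partner_is_monophyletic():
    t = oc.PhyloTree.from_newick("((A,B),(C,D),(E,F));", list("ABCDEF"))
    og = _taxonset(t, ["F"], "og")
    assert oc.is_monophyletic(t, _taxonset(t, ["A", "B"]), og)
    assert not oc.is_monophyletic(t, _taxonset(t, ["A", "C"]), og)


def test_group_spanning_root_not_monophyletic():
    t = oc.PhyloTree.from_newick("((A,B),(C,D),(E,F));", list("ABCDEF"))
    og = _taxonset(t, ["C", "D"], "og")
    # {A, E} spans both sides of the outgroup-rooted tree
    assert not oc.is_monophyletic(t, _taxonset(t, ["A", "E"]), og)


def test_monophyly_overlap_with_outgroup_rejected():
    t = oc.simulate_tree(6, seed=0)
    og = _taxonset(t, [t.taxa[0]], "og")
    with pytest.raises(ValueError):
        oc.is_monophyletic(t, _taxonset(t, [t.taxa[0], t.taxa[1]]), og)


@pytest.mark.parametrize("seed", range(10))
def test_monophyly_agrees_with_rooted_traversal_oracle(seed):
    """Random trees and groups versus a root-then-traverse oracle
    built on dendropy."""
    import dendropy
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 10))
    tree = oc.simulate_tree(n, seed=seed)
    og = _taxonset(tree, [tree.taxa[0]], "og")
    dtree = dendropy.Tree.get(data=tree.to_newick(root_on=tree.taxa[0]),
                              schema="newick", preserve_underscores=True)
    dtree.is_rooted = True
    for _ in range(8):
        size = int(rng.integers(2, n - 1))
        group = list(rng.choice(tree.taxa[1:], size=size, replace=False))
        mine = oc.is_monophyletic(tree, _taxonset(tree, group), og)
        mrca = dtree.mrca(taxon_labels=group)
        oracle = (len(mrca.leaf_nodes()) == len(group))
        assert mine == oracle


def test_overlapping_groups_rejected():
    a = oc.TaxonSet("a", frozenset(["x", "y"]))
    b = oc.TaxonSet("b", frozenset(["y", "z"]))
    with pytest.raises(ValueError):
        oc.ConstraintSpec([a, b])
    # nested groups are fine
    oc.ConstraintSpec([oc.TaxonSet("a", frozenset(["x", "y"])),
                       oc.TaxonSet("b", frozenset(["x", "y", "z"]))])


def test_empty_spec_equals_unconstrained(beetle_matrix):
    cfg = oc.SearchConfig(replicates=5, seed=1)
    a = oc.constrained_search(beetle_matrix, oc.ConstraintSpec([]), cfg)
    b = oc.tbr_search(beetle_matrix, cfg)
    assert a.best_length == b.best_length
    assert {t.splits for t in a.binary_trees} == \
        {t.splits for t in b.binary_trees}


@pytest.mark.parametrize("seed", range(5))
def test_constrained_never_shorter_and_all_satisfy(seed):
    matrix, tree = random_small_matrix(300 + seed, n_taxa=8)
    og = oc.TaxonSet("og", frozenset([matrix.taxa[0]]))
    rng = np.random.default_rng(seed)
    group = oc.TaxonSet("g", frozenset(
        rng.choice(matrix.taxa[1:], size=3, replace=False)))
    cfg = oc.SearchConfig(replicates=8, seed=seed)
    free = oc.tbr_search(matrix, cfg)
    constrained = oc.constrained_search(matrix, oc.ConstraintSpec([group]),
                                        cfg)
    assert constrained.best_length >= free.best_length
    assert oc.step_difference(constrained, free) == \
        constrained.best_length - free.best_length
    for t in constrained.binary_trees:
        assert oc.is_monophyletic(t, group, og)


def test_relaxing_a_spec_never_increases_length(beetle_matrix):
    cfg = oc.SearchConfig(replicates=20, seed=4)
    g1 = oc.constraint_group("Tetraphalerus", "Odontomma")
    g2 = oc.constraint_group("Pareuryomma", "Notocupes")
    both = oc.constrained_search(beetle_matrix, oc.ConstraintSpec([g1, g2]),
                                 cfg)
    one = oc.constrained_search(beetle_matrix, oc.ConstraintSpec([g1]), cfg)
    assert one.best_length <= both.best_length


def test_already_satisfied_constraint_costs_nothing(beetle_matrix):
    """Enforcing a clade of the strict consensus changes nothing."""
    cfg = oc.SearchConfig(replicates=20, seed=6)
    free = oc.tbr_search(beetle_matrix, cfg)
    cons = oc.strict_consensus(free.binary_trees)
    mask = max(cons.splits, key=lambda s: bin(s).count("1"))
    labels = [t for i, t in enumerate(beetle_matrix.taxa) if mask >> i & 1]
    group = beetle_matrix.taxon_set("consensus_clade", labels)
    res = oc.constrained_search(beetle_matrix, oc.ConstraintSpec([group]),
                                cfg)
    assert oc.step_difference(res, free) == 0


def test_step_difference_negative_is_internal_error():
    cfg = oc.SearchConfig(replicates=2, seed=0)
    matrix, _ = random_small_matrix(1, n_taxa=6)
    a = oc.tbr_search(matrix, cfg)
    b = oc.tbr_search(matrix, cfg)
    b.best_length += 1  # simulate a broken search
    with pytest.raises(RuntimeError):
        oc.step_difference(a, b)
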