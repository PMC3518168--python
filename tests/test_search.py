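"""Wagner starts, TBR search, branch-and-bound and collapsing."""

import numpy as np
import pytest

import ommclad as oc
from ommclad.matrix import CharacterDefinition, CharacterMatrix

from conftest import random_small_matrix


def _matrix(rows, n_states=2, taxa=None):
    rows = np.array(rows, dtype=np.int8)
    taxa = taxa or [chr(65 + i) for i in range(rows.shape[0])]
    chars = [CharacterDefinition(j, n_states=n_states)
             for j in range(rows.shape[1])]
    return CharacterMatrix(taxa, chars, rows)


def test_wagner_three_taxa_unique_topology():
    m = _matrix([[0], [1], [1]])
    t = oc.wagner_addition(m)
    assert t.n_taxa == 3 and len(t.splits) == 0


def test_wagner_too_few_taxa():
    with pytest.raises(ValueError):
        oc.wagner_addition(_matrix([[0], [1]]))


def test_wagner_deterministic_given_seed():
    matrix, _ = random_small_matrix(5, n_taxa=8)
    order = list(range(8))
    a = oc.wagner_addition(matrix, order=order, seed=123)
    b = oc.wagner_addition(matrix, order=order, seed=123)
    assert a.splits == b.splits
    assert np.array_equal(a.adjacency(), b.adjacency())


def test_wagner_attains_optimum_on_clean_matrix():
    """On a homoplasy-free 6-taxon matrix greedy addition reaches the
    generating tree's (optimal) length."""
    truth = oc.simulate_tree(6, seed=4)
    matrix = oc.simulate_matrix(truth, oc.SimConfig(
        n_taxa=6, n_characters=20, expected_changes=0.8,
        missing_fraction=0.0, inapplicable_fraction=0.0, seed=4))
    score_truth = oc.fitch_length(truth, matrix)
    if score_truth.ci() == 1.0:  # clean regime
        bb = oc.branch_and_bound(matrix)
        w = oc.wagner_addition(matrix, seed=0)
        assert oc.fitch_length(w, matrix).length == bb.best_length


@pytest.mark.parametrize("seed", range(8))
def test_tbr_matches_branch_and_bound(seed):
    matrix, _ = random_small_matrix(40 + seed)
    bb = oc.branch_and_bound(matrix)
    hs = oc.tbr_search(matrix, oc.SearchConfig(replicates=10, seed=seed))
    assert hs.best_length == bb.best_length
    # with the equal-length closure the heuristic finds the complete
    # set of optimal binary trees
    assert ({t.splits for t in hs.binary_trees}
            == {t.splits for t in bb.binary_trees})


def test_branch_and_bound_matches_exhaustive_seven_taxa():
    from conftest import all_topologies, brute_force_length, tree_from_edges
    matrix, _ = random_small_matrix(77, n_taxa=7, n_chars=4)
    topos = all_topologies(7)
    assert len(topos) == 945
    best = min(brute_force_length(e, matrix) for e in topos)
    bb = oc.branch_and_bound(matrix)
    assert bb.best_length == best


def test_branch_and_bound_refuses_large_matrices(beetle_matrix):
    with pytest.raises(ValueError):
        oc.branch_and_bound(beetle_matrix)


def test_bound_property(beetle_matrix):
    sub = beetle_matrix.subset_taxa(beetle_matrix.taxa[:8])
    bb = oc.branch_and_bound(sub)
    hs = oc.tbr_search(sub, oc.SearchConfig(replicates=5, seed=0))
    assert bb.best_length <= hs.best_length


def test_retained_trees_all_score_best(beetle_matrix):
    res = oc.tbr_search(beetle_matrix, oc.SearchConfig(replicates=10, seed=3))
    for t in res.binary_trees[:25]:
        assert oc.fitch_length(t, beetle_matrix).length == res.best_length


def test_seeded_runs_reproducible(beetle_matrix):
    a = oc.tbr_search(beetle_matrix, oc.SearchConfig(replicates=5, seed=9))
    b = oc.tbr_search(beetle_matrix, oc.SearchConfig(replicates=5, seed=9))
    assert a.best_length == b.best_length
    assert [t.splits for t in a.binary_trees] == [t.splits for t in b.binary_trees]


def test_seeds_agree_on_fixture_best_length(beetle_matrix):
    lengths = {oc.tbr_search(beetle_matrix,
                             oc.SearchConfig(replicates=30, seed=s)).best_length
               for s in range(5)}
    assert len(lengths) == 1


def test_tbr_plateau_connects_all_topologies():
    """On a constant matrix every 6-taxon topology is an equally
    optimal tree; closure under equal-length TBR moves must enumerate
    all 105 of them (enumeration oracle)."""
    m = _matrix([[0]] * 6)
    res = oc.tbr_search(m, oc.SearchConfig(replicates=1, seed=0, hold=500))
    assert res.best_length == 0
    assert len(res.binary_trees) == 105


def test_collapse_fully_supported_tree_unchanged():
    truth = oc.simulate_tree(6, seed=11)
    matrix = oc.simulate_matrix(truth, oc.SimConfig(
        n_taxa=6, n_characters=40, expected_changes=1.2,
        missing_fraction=0.0, inapplicable_fraction=0.0, seed=11))
    if all(truth.has_split(s) for s in
           oc.collapse(truth, matrix, "max_zero").splits):
        # every internal edge carries at least one change in all MPRs?
        cmin = oc.collapse(truth, matrix, "min_zero")
        if len(cmin.splits) == len(truth.splits):
            assert cmin.splits == truth.splits


def test_collapse_star_matrix():
    m = _matrix([[oc.MISSING]] * 6)
    t = oc.simulate_tree(6, seed=2)
    m = CharacterMatrix(list(t.taxa), m.characters, m.cells)
    assert len(oc.collapse(t, m, "min_zero").splits) == 0


@pytest.mark.parametrize("seed", range(6))
def test_min_zero_collapses_at_least_max_zero(seed):
    matrix, tree = random_small_matrix(60 + seed, n_taxa=6)
    cmin = oc.collapse(tree, matrix, "min_zero")
    cmax = oc.collapse(tree, matrix, "max_zero")
    assert cmin.splits <= cmax.splits
    assert oc.collapse(tree, matrix, "none").splits == tree.splits


def test_min_zero_strictly_more_on_ambiguous_case():
    """A character whose optimization is ambiguous yields an edge that
    min_zero contracts but max_zero keeps."""
    # A,B = 0; E,F = 1; C,D uninformative: on ((A,B),(C,D),(E,F)) the
    # central edges have MPRs with and without changes.
    m = _matrix([[0, 0], [0, 0], [0, 1], [1, 0], [1, 1], [1, 1]])
    t = oc.PhyloTree.from_newick("(((A,B),(C,D)),(E,F));", m.taxa)
    cmin = oc.collapse(t, m, "min_zero")
    cmax = oc.collapse(t, m, "max_zero")
    assert cmin.splits < cmax.splits
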