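"""Fitch scoring, step bounds and ensemble indices."""

import numpy as np
import pytest

import ommclad as oc
from ommclad.matrix import CharacterDefinition, CharacterMatrix
from ommclad.parsimony import (char_max_steps, char_min_steps,
                               ensemble_indices)

from conftest import brute_force_length, random_small_matrix, tree_from_edges


def _matrix(rows, n_states=2, taxa=None):
    rows = np.array(rows, dtype=np.int8)
    taxa = taxa or [chr(65 + i) for i in range(rows.shape[0])]
    chars = [CharacterDefinition(j, n_states=n_states)
             for j in range(rows.shape[1])]
    return CharacterMatrix(taxa, chars, rows)


def test_single_character_one_step():
    m = _matrix([[0], [0], [1], [1]])
    tree = oc.PhyloTree.from_newick("((A,B),(C,D));", m.taxa)
    assert oc.fitch_length(tree, m).length == 1


def test_all_missing_scores_zero():
    m = _matrix([[oc.MISSING]] * 5)
    tree = oc.simulate_tree(5, seed=0)
    m = CharacterMatrix(list(tree.taxa), m.characters, m.cells)
    assert oc.fitch_length(tree, m).length == 0


@pytest.mark.parametrize("seed", range(12))
def test_fitch_equals_exhaustive_enumeration(seed):
    """Kernel Fitch counts match brute-force minimisation over all
    internal state assignments (random 5-8 taxon matrices with missing
    and inapplicable cells, including a 3-state character)."""
    matrix, tree = random_small_matrix(seed)
    n = matrix.n_taxa
    adj = tree.adjacency()
    edges = [(a, int(adj[a, k])) for a in range(adj.shape[0])
             for k in range(3) if int(adj[a, k]) > a]
    assert oc.fitch_length(tree, matrix).length == \
        brute_force_length(edges, matrix)


def test_invariant_under_taxon_and_character_reorder():
    matrix, tree = random_small_matrix(99, n_taxa=7)
    base = oc.fitch_length(tree, matrix).length
    rng = np.random.default_rng(0)
    perm = rng.permutation(matrix.n_taxa)
    taxa2 = [matrix.taxa[i] for i in perm]
    m2 = matrix.subset_taxa(taxa2)
    cperm = rng.permutation(matrix.n_characters)
    m3 = CharacterMatrix(taxa2,
                         [CharacterDefinition(j, n_states=m2.characters[c].n_states)
                          for j, c in enumerate(cperm)],
                         m2.cells[:, cperm])
    assert oc.fitch_length(tree, m3).length == base


def test_invariant_under_display_rerooting():
    matrix, tree = random_small_matrix(7, n_taxa=6)
    base = oc.fitch_length(tree, matrix).length
    for taxon in tree.taxa:
        rerooted = oc.PhyloTree.from_newick(tree.to_newick(root_on=taxon),
                                            tree.taxa)
        assert oc.fitch_length(rerooted, matrix).length == base


def test_adding_characters_never_decreases_length():
    matrix, tree = random_small_matrix(3, n_taxa=6, n_chars=8)
    lengths = []
    for j in range(1, matrix.n_characters + 1):
        sub = CharacterMatrix(
            matrix.taxa,
            [CharacterDefinition(i, n_states=matrix.characters[i].n_states)
             for i in range(j)],
            matrix.cells[:, :j])
        lengths.append(oc.fitch_length(tree, sub).length)
    assert all(b >= a for a, b in zip(lengths, lengths[1:]))


def test_char_min_steps():
    assert char_min_steps(np.array([0, 1, 2, 1])) == 2
    assert char_min_steps(np.array([1, 1, 1])) == 0
    assert char_min_steps(np.array([0, 1, oc.MISSING, oc.MISSING])) == 1


def test_char_max_steps():
    assert char_max_steps(np.array([0, 0, 0, 1, 1])) == 2
    assert char_max_steps(np.array([0, 0, 0])) == 0
    assert char_max_steps(np.array([0] * 5 + [1] * 3)) == 3
    assert char_max_steps(np.array([oc.MISSING] * 4)) == 0


def test_ensemble_indices_homoplasy_free():
    m = _matrix([[0], [0], [1], [1]])
    tree = oc.PhyloTree.from_newick("((A,B),(C,D));", m.taxa)
    score = oc.fitch_length(tree, m)
    ci, ri = ensemble_indices(score.observed, score.min_steps,
                              score.max_steps)
    assert ci == 1.0 and ri == 1.0


def test_ci_below_one_reflects_homoplasy():
    m = _matrix([[0], [1], [0], [1]])
    tree = oc.PhyloTree.from_newick("((A,B),(C,D));", m.taxa)
    score = oc.fitch_length(tree, m)
    assert score.length == 2
    assert score.ci() == 0.5


@pytest.mark.parametrize("seed", range(6))
def test_indices_match_per_character_recomputation(seed):
    """CI/RI from the score equal an independent recomputation from
    per-character brute-force s, m, g on a random 7-taxon matrix."""
    matrix, tree = random_small_matrix(200 + seed, n_taxa=7)
    score = oc.fitch_length(tree, matrix)
    n = matrix.n_taxa
    adj = tree.adjacency()
    edges = [(a, int(adj[a, k])) for a in range(adj.shape[0])
             for k in range(3) if int(adj[a, k]) > a]
    s = m_ = g = 0
    for j in range(matrix.n_characters):
        sub = CharacterMatrix(
            matrix.taxa, [CharacterDefinition(0, n_states=matrix.characters[j].n_states)],
            matrix.cells[:, [j]])
        s += brute_force_length(edges, sub)
        m_ += char_min_steps(matrix.column(j))
        g += char_max_steps(matrix.column(j))
    if s:
        assert score.ci() == pytest.approx(m_ / s)
    if g != m_:
        assert score.ri() == pytest.approx((g - s) / (g - m_))


def test_score_on_collapsed_tree_matches_binary():
    """The polytomy-capable scorer agrees with the kernel on binary
    trees and is well defined after collapsing."""
    matrix, tree = random_small_matrix(31, n_taxa=7)
    binary = oc.fitch_length(tree, matrix).length
    poly = oc.collapse(tree, matrix, "min_zero")
    assert oc.fitch_length(poly, matrix).length >= binary
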