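"""Parsimony scores and homoplasy indices.

Tree length is the minimum number of state changes summed over
characters (Fitch counts for unordered characters; cells scored as the
full state set where missing or inapplicable).  The ensemble indices
follow the standard definitions

    CI = sum(m_i) / sum(s_i)        (consistency index)
    RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i))   (retention index)

with, per character i, ``s_i`` the observed steps on the tree, ``m_i``
the minimum steps on any tree (number of observed states minus one) and
``g_i`` the maximum steps on any tree (steps on the star tree: scored
taxa minus the frequency of the commonest state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .matrix import CharacterMatrix
from .tree import PhyloTree, popcount

__all__ = ["ParsimonyScore", "fitch_length", "char_min_steps",
           "char_max_steps", "ensemble_indices", "round_half_up"]

_INF = 1 << 30


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding with ties away from zero (0.505 -> 0.51)."""
    scale = 10 ** digits
    return np.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length with per-character step decomposition."""

    length: int
    observed: tuple[int, ...]   # s_i
    min_steps: tuple[int, ...]  # m_i
    max_steps: tuple[int, ...]  # g_i

    @property
    def per_character(self) -> list[tuple[int, int, int]]:
        return list(zip(self.observed, self.min_steps, self.max_steps))

    def ci(self, include_uninformative: bool = True) -> float:
        return ensemble_indices(self.observed, self.min_steps,
                                self.max_steps, include_uninformative)[0]

    def ri(self, include_uninformative: bool = True) -> float | None:
        return ensemble_indices(self.observed, self.min_steps,
                                self.max_steps, include_uninformative)[1]


def char_min_steps(column: np.ndarray) -> int:
    """Minimum steps of a character on any tree."""
    observed = np.unique(column[np.asarray(column) >= 0])
    return max(len(observed) - 1, 0)


def char_max_steps(column: np.ndarray) -> int:
    """Maximum steps of a character on any tree (star-tree steps)."""
    column = np.asarray(column)
    vals, counts = np.unique(column[column >= 0], return_counts=True)
    if len(vals) == 0:
        return 0
    return int(counts.sum() - counts.max())


def ensemble_indices(observed, min_steps, max_steps,
                     include_uninformative: bool = True
                     ) -> tuple[float, float | None]:
    """(CI, RI) over a set of characters.

    With ``include_uninformative=False``, characters whose maximum and
    minimum possible steps coincide (they cannot show homoplasy) are
    dropped; this only affects CI, since such characters cancel from
    both RI sums.  RI is None when sum(g) == sum(m).
    """
    s = np.asarray(observed, dtype=float)
    m = np.asarray(min_steps, dtype=float)
    g = np.asarray(max_steps, dtype=float)
    if not include_uninformative:
        keep = g > m
        s, m, g = s[keep], m[keep], g[keep]
    if s.sum() == 0:
        raise ValueError("all characters are constant: CI undefined")
    ci = float(m.sum() / s.sum())
    ri = None if g.sum() == m.sum() else float((g.sum() - s.sum())
                                               / (g.sum() - m.sum()))
    return ci, ri


def _sankoff_steps(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum changes on ``tree`` (handles polytomies).

    Unit-cost dynamic programming over states; exact for unordered
    characters and equal to the Fitch count on binary trees.  Serves as
    the scoring path for arbitrary (possibly collapsed) trees and as an
    independent cross-check of the bitwise kernels.
    """
    n = matrix.n_taxa
    full = (1 << n) - 1
    # children structure, rooted at taxon 0
    clades = sorted(tree.splits, key=popcount)
    ingroup = full ^ 1
    nodes: list[tuple[int, list]] = [(1 << i, []) for i in range(1, n)]
    for cl in clades + [ingroup]:
        inside = [nd for nd in nodes if nd[0] & cl]
        outside = [nd for nd in nodes if not (nd[0] & cl)]
        mask = 0
        for mm, _ in inside:
            mask |= mm
        nodes = outside + [(mask, inside)]
    root_children = nodes  # plus leaf 0 handled at the end

    masks = matrix.state_masks()
    out = np.zeros(matrix.n_characters, dtype=np.int64)
    for j, ch in enumerate(matrix.characters):
        k = ch.n_states

        def cost(node) -> np.ndarray:
            mask, children = node
            if not children:
                leaf = mask.bit_length() - 1
                vec = np.full(k, _INF)
                for s in range(k):
                    if (masks[leaf, j] >> s) & 1:
                        vec[s] = 0
                return vec
            vec = np.zeros(k)
            for childnode in children:
                c = cost(childnode)
                vec = vec + np.minimum(c, c.min() + 1)
            return vec

        total = np.zeros(k)
        for childnode in root_children:
            c = cost(childnode)
            total = total + np.minimum(c, c.min() + 1)
        allowed = np.array([(masks[0, j] >> s) & 1 == 1 for s in range(k)])
        out[j] = int(total[allowed].min())
    return out


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix,
                 include_uninformative: bool = True) -> ParsimonyScore:
    """Score ``tree`` against ``matrix``.

    The tree's leaves must equal the matrix's taxa (a proper subset is
    accepted; the matrix is restricted to it).  Binary trees go through
    the fast bitwise kernel; trees with polytomies through the
    state-wise dynamic program.
    """
    tset, mset = set(tree.taxa), set(matrix.taxa)
    if tset != mset:
        if tset < mset:
            matrix = matrix.subset_taxa(list(tree.taxa))
        else:
            diff = sorted(tset ^ mset)
            raise ValueError(f"tree/matrix taxon mismatch: {diff}")
    elif list(tree.taxa) != matrix.taxa:
        matrix = matrix.subset_taxa(list(tree.taxa))

    if tree.is_binary() and tree.n_taxa >= 3:
        observed = np.empty(matrix.n_characters, dtype=np.int64)
        _kernels.fitch_per_character(tree.adjacency(), matrix.state_masks(),
                                     0, observed)
    else:
        observed = _sankoff_steps(tree, matrix)
    m = tuple(char_min_steps(matrix.column(j))
              for j in range(matrix.n_characters))
    g = tuple(char_max_steps(matrix.column(j))
              for j in range(matrix.n_characters))
    return ParsimonyScore(int(observed.sum()), tuple(int(x) for x in observed),
                          m, g)
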