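# Methods

## The model

All characters are treated as unordered (non-additive) and equally
weighted: any state may change into any other at cost 1.  The score of
a tree is its Fitch length — the minimum number of state changes over
all assignments of states to internal nodes, summed over characters.
Missing (`?`) and inapplicable (`-`) cells are stored distinctly for
the data model and file round-trips, but both are scored as the full
state set of their character; no reductive or hierarchical coding of
inapplicables is attempted.  Per character, `m` (observed states − 1)
and `g` (scored taxa − frequency of the commonest state) bound the
steps attainable on any tree, giving the ensemble indices
CI = Σm/Σs and RI = (Σg−Σs)/(Σg−Σm).  CI and RI include uninformative
characters by default (a flag excludes them; only CI is affected — in
RI such characters cancel).  Displayed values are rounded half-up to
two decimals.

## Scoring and search machinery

Character data are bitmask-encoded (≤ 8 states) and all inner loops
are JIT-compiled.  The heuristic search is the classic two-phase
strategy: each replicate builds a random-addition Wagner tree (ties
among equally good insertion edges broken by a seeded uniform draw)
and takes it to a local optimum by steepest-descent TBR; after all
replicates, a closure pass swaps every retained optimal tree and
harvests all equal-length TBR neighbours until no new topology
appears or the `hold` buffer (default 10000) fills.  TBR is scored
in O(#characters) per reconnection by precomputing, for every edge of
both bisection components, the Fitch state set and cost of the
component rooted on that edge; joining two rooted components then
costs one set intersection per character.  Trees are identified by
their sets of leaf bipartitions, so deduplication and consensus are
set arithmetic on integer masks.

Zero-length internal branches are contracted before
most-parsimonious-tree counts are reported.  Two rules are available,
because the counts (unlike the lengths) depend on the choice:
`min_zero` (default) contracts an edge if *some* most parsimonious
reconstruction places zero changes on it — the behaviour of the
"ambiguous-collapse" setting in classic parsimony programs — while
`max_zero` contracts only edges with zero changes in *every* MPR.
Both tests are computed exactly per edge from directional per-state
cost vectors (unit-cost dynamic programming up and down the tree).

`branch_and_bound` enumerates trees by stepwise addition with
pruning (adding a taxon never shortens a tree) and returns provably
all minimum-length binary trees; it refuses matrices over 12 taxa.
It is the exact oracle against which the heuristic is tested.

Constrained searches enforce monophyly as hard filters: Wagner
insertion positions that would break a required group are skipped, as
are TBR reconnections, so the search never leaves the constrained
space.  Overlapping (non-nested) groups are rejected as
unsatisfiable.  Bremer support runs one converse-constraint search
per clade — trees in which the clade must *not* appear — rather than
pooling suboptimal trees, because pooling under a hold limit
understates decay; values are still upper bounds whenever the
converse search is heuristic, and they can reach 0 for clades that
survive in the consensus only because the binary tree buffer was
capped.

## The packaged beetle matrix

The 28-taxon × 28-character Ommatidae matrix is generated from
explicit per-character coding rules (genus-level state lists, defaults
for exhaustively phrased contrasts, species-level overrides), each
carrying a condensed source note; `provenance_table()` exports the
rules and the shipped `data/ommatidae_provenance.tsv` mirrors them.
Decisions a reader may want to audit:

* Character 4 (gular sutures) is the single three-state character.
* The labrum/clypeus ratio is inapplicable in *Omma* (labrum fused
  with the clypeus); window-puncture size is inapplicable where the
  elytral disk lacks window punctures.  The labrum's anterior margin
  is nevertheless scored for extant *Omma*, following the source
  coding.
* "Not recognisable/visible" statements about compression fossils
  become `?`; statements about extant material become real absence
  states.
* *Zygadenia* is scored strictly from the per-character lists; where
  it is omitted from a list that names *Notocupes*, the cell is `?`.
  The constraint-group builder exposes a sensitivity flag that adds
  *Zygadenia* to a *Notocupes* group (off by default).

About 9% of cells are `?` and 2% `-`.  Because several fossil taxa
are known only from genus-level statements, this matrix is somewhat
more ambiguous than a matrix scored directly from specimens would be;
tree *lengths* (unconstrained and constrained optima) are robust to
that ambiguity, whereas the *number* of distinct optimal trees and
the resolution of the strict consensus are highly sensitive to it —
wildcard taxa multiply equally optimal placements.  MPT counts are
therefore reported under both collapse rules rather than asserted,
and consensus claims should be read against the reported counts.

## The simulator

`simulate_tree` draws topologies uniformly (random sequential
addition on a uniformly chosen edge); `simulate_matrix` evolves each
character independently under the symmetric k-state (Mk) chain with
equal branch lengths, parameterised by the expected number of changes
per character summed over the tree, then masks cells at the
configured missing/inapplicable rates.  Defaults mirror the packaged
matrix: 28 taxa, 28 characters, one 3-state character, 10% missing,
1% inapplicable, and two expected changes per character, which
reproduces a comparable homoplasy level (CI near 0.5).

What passing simulation tests show — and what they do not: the
generator exercises fixture-scale shapes, missing data and
multistate characters, so it validates the scoring, search and
consensus machinery end to end; it does not emulate correlated
characters, ascertainment bias against constant characters,
rate heterogeneity across lineages, or structured (anatomically
clustered) inapplicability, so good performance here does not by
itself certify behaviour on real morphological data.

The recovery study uses 0.04 expected changes per character over 100
characters: with a Poisson number of changes, the chance any
character changes twice is ≈ 8 in 10000, so about 92% of replicates
are expected to be fully homoplasy-free — a regime where the
generating tree must be among the optimal trees and CI = 1.

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds (replicate
  addition orders, Wagner tie-breaks, simulation); seeded runs are
  bit-reproducible, and the seed is echoed in `SearchResult.config`.
* Steepest-descent TBR takes the first of equally best improving
  moves in scan order; plateau exploration is deferred to the closure
  pass.
* The `hold` buffer caps retained *binary* trees; when it fills
  (flagged in `SearchResult.hold_hit`) collapsed-tree counts and the
  consensus are computed from the capped pool, exactly as classic
  programs behave at their tree-buffer limit.
* Problem sizes used by the packaged validation runs: oracle
  equivalence on 6–8-taxon matrices (exhaustive enumeration up to 945
  topologies, brute-force state assignment), fixture-scale searches
  at 1000 replicates, and 50 simulation replicates at 28 × 100.

## Known limitations

Ordered/Sankoff characters, implied weighting and resampling support
measures are out of scope.  Branch-and-bound is practical only to
~12 taxa.  Constrained Wagner construction requires constraint groups
to be disjoint or nested.  The TBR neighbourhood is scanned fully at
each step (no neighbourhood sampling), which is fine at 28 taxa but
would need revisiting beyond ~100.
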