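"""Heuristic search for most parsimonious trees.

Runs a random-addition + TBR search on the Ommatidae matrix (reduced
replicate count for a quick demonstration; the full analysis uses
1000) and prints the best length, the number of distinct most
parsimonious trees under both zero-length-branch collapsing rules, and
the strict consensus rooted on the permocupedid outgroup.
"""

import ommclad as oc

matrix = oc.ommatidae_matrix()
res = oc.tbr_search(matrix, oc.SearchConfig(replicates=50, seed=42))
score = oc.fitch_length(res.binary_trees[0], matrix)

print(f"best tree length: {res.best_length} steps")
print(f"ensemble CI {score.ci():.2f}, RI {score.ri():.2f}")
print(f"retained binary trees: {len(res.binary_trees)}"
      + (" (hold limit reached)" if res.hold_hit else ""))
print(f"distinct MPTs, min_zero collapsing: {res.n_trees}")

res_max = oc.tbr_search(matrix, oc.SearchConfig(replicates=50, seed=42,
                                                collapse_rule="max_zero"))
print(f"distinct MPTs, max_zero collapsing: {res_max.n_trees}")

cons = oc.strict_consensus(res.binary_trees)
print("strict consensus (rooted on the outgroup):")
print(cons.to_newick(root_on="Permocupes_sojanensis"))
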