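"""Score a starting tree on the beetle matrix.

Builds a Wagner (greedy stepwise-addition) tree for the packaged
28-taxon Ommatidae matrix and reports its parsimony score: the tree
length (total state changes), the ensemble consistency index
CI = sum(m)/sum(s) and retention index RI = (sum(g)-sum(s))/(sum(g)-sum(m)).
A CI of 1 would mean a homoplasy-free fit; morphological matrices
typically land near 0.5.
"""

import ommclad as oc

matrix = oc.ommatidae_matrix()
tree = oc.wagner_addition(matrix, seed=1)
score = oc.fitch_length(tree, matrix)

print(f"matrix: {matrix.n_taxa} taxa x {matrix.n_characters} characters")
print(f"Wagner tree length: {score.length} steps")
print(f"ensemble CI: {score.ci():.3f}   ensemble RI: {score.ri():.3f}")
worst = max(range(matrix.n_characters),
            key=lambda j: score.observed[j] - score.min_steps[j])
print(f"most homoplastic character: #{worst} "
      f"({matrix.characters[worst].label}), "
      f"{score.observed[worst]} steps vs minimum {score.min_steps[worst]}")
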