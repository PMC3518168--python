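"""Bremer (decay) support for the consensus clades.

For each clade of the strict consensus, searches for the shortest tree
in which that clade does not appear; the decay value is the extra
length required.  Higher values mean better-supported clades; a clade
present in all MPTs has decay >= 1.  Converse-constraint searches are
heuristic, so the values are upper bounds.
"""

import ommclad as oc

matrix = oc.ommatidae_matrix()
res = oc.tbr_search(matrix, oc.SearchConfig(replicates=50, seed=5))
cons = oc.strict_consensus(res.binary_trees)
print(f"best length {res.best_length}; consensus has {len(cons.splits)} clades")

table = oc.bremer_support(matrix, cons, oc.SearchConfig(replicates=10, seed=5),
                          best_length=res.best_length)
for row in table.to_rows():
    print(f"decay {row['decay']:>2}  {row['clade']}")
print()
print("consensus with decay values as node labels:")
print(table.annotated_newick(root_on="Permocupes_sojanensis"))
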