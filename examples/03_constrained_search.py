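"""Constrained searches testing proposed genus synonymies.

Forces the monophyly of Tetraphalerus+Odontomma and of
Pareuryomma+Notocupes (separately and jointly) and reports how many
extra steps each constraint demands over the unconstrained optimum.
A large step excess means the matrix disfavours the grouping.
"""

import ommclad as oc

matrix = oc.ommatidae_matrix()
config = oc.SearchConfig(replicates=50, seed=7)

base = oc.tbr_search(matrix, config)
print(f"unconstrained best length: {base.best_length}")

g_to = oc.constraint_group("Tetraphalerus", "Odontomma")
g_pn = oc.constraint_group("Pareuryomma", "Notocupes")

for label, groups in [("Tetraphalerus+Odontomma", [g_to]),
                      ("Pareuryomma+Notocupes", [g_pn]),
                      ("both jointly", [g_to, g_pn])]:
    res = oc.constrained_search(matrix, oc.ConstraintSpec(groups), config)
    extra = oc.step_difference(res, base)
    score = oc.fitch_length(res.binary_trees[0], matrix)
    print(f"{label}: length {res.best_length} (+{extra} steps), "
          f"{res.n_trees} MPTs, CI {score.ci():.2f}, RI {score.ri():.2f}")
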