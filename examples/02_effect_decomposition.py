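"""Decompose standardized effects into direct, indirect and total parts.

The total effect of a predictor on an outcome in a recursive path model is
(I - B)^-1 - I evaluated on the standardized coefficient matrix B; the
indirect part is the sum of coefficient products over all mediating paths,
which `enumerate_paths` lists explicitly.
"""

import cardiosem as cs

study = cs.fit_study(compute_se=False)
eff = study.effects.table
show = eff[eff.predictor.isin(["LifetimeAbuse", "DepSlope", "Smoking",
                               "BodyWeight", "Age"])]
print(show.round(3).to_string(index=False))
print()

B = cs.structural_coefficient_matrix(study.result)
print("Mediation routes from LifetimeAbuse to CVDRisk:")
for path, prod in cs.enumerate_paths(B, "LifetimeAbuse", "CVDRisk"):
    kind = "direct " if len(path) == 2 else "via " + " -> ".join(path[1:-1])
    print(f"  {prod:+.4f}  {kind}")
print()
print("The products over all routes sum to the total effect; routes of")
print("length >= 2 sum to the indirect effect (total = direct + indirect).")
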