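"""Assign SMIRKS-typed DE parameters to ethanol by direct chemical perception.

Each library record pairs a SMIRKS pattern (one tagged atom) with
(epsilon, r_m); the last matching record wins, so the generic hydrogen type
is refined to a polar type for the hydroxyl hydrogen.  Note the polar
hydrogen carries epsilon = 0: its vdW term is removed entirely.
"""

from deff import MolecularGraph, assign_parameters, fixture_library

library = fixture_library()
ethanol = MolecularGraph.from_smiles("CCO")
params, labels = assign_parameters(ethanol, library)

print(f"{'atom':>4} {'element':>8} {'type':>12} {'epsilon':>9} {'r_m':>7}")
for i, (el, lab, p) in enumerate(zip(ethanol.elements, labels, params)):
    print(f"{i:4d} {el:>8} {lab:>12} {p.epsilon:9.4f} {p.r_m:7.2f}")
print()
print("The hydroxyl H gets the polar record (epsilon=0, vdW removed);")
print("the five C-H hydrogens keep the aliphatic type.")
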