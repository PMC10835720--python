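"""MM/PBSA energy ledger: totals, relative energies, affinity ranking.

Loads the published binding-energy components (van der Waals,
electrostatic, polar and nonpolar solvation) of the five 1:1
pigment/copigment complexes, sums them to the binding enthalpy with
propagated SEMs, and ranks the copigments, flagging statistically
indistinguishable pairs.
"""

import copigkit as ck

decomps = ck.reference.mmpbsa_reference()

print(f"{'compound':14s} {'dH_binding (cal/mol)':>22s} {'SEM':>8s} {'ddH':>8s}")
rel = ck.relative_binding(decomps)
for d in sorted(decomps, key=lambda x: x.total):
    print(f"{d.label:14s} {d.total:22.0f} {d.total_sem:8.0f} {rel[d.label]:8.0f}")

ranking = ck.rank_affinity(decomps)
print(f"\naffinity order: {ranking}")
print(
    "Quercetin binds most strongly (ddH = 0 reference); epicatechin ranks "
    "above catechin, while gallic and caffeic acid differ by less than "
    "their combined SEM and are flagged as a tie."
)
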