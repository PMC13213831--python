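"""Decompose a ligand edge into membrane and protein contributions.

The same alchemical transformation run in water, membrane and
membrane-embedded protein closes three thermodynamic cycles, splitting
the observed relative binding free energy into a membrane-partitioning
part and a protein-interaction part.
"""

from neqcycle import FreeEnergyEstimate, decompose


def est(v, e):
    return FreeEnergyEstimate(v, e, "bar")


dec = decompose(
    dG_w=est(0.0, 0.1),      # transformation free energy in water
    dG_m=est(-2.6, 0.3),     # ... in the lipid bilayer
    dG_p=est(-5.6, 0.2),     # ... bound to the membrane-embedded protein
    ligand_from="11a", ligand_to="11b",
)

print(f"edge {dec.edge}")
print(f"  ΔΔG_obs = {dec.ddG_obs:+.2f} ± {dec.err_obs:.2f} kcal/mol  (protein − water)")
print(f"  ΔΔG_int = {dec.ddG_int:+.2f} ± {dec.err_int:.2f} kcal/mol  (protein − membrane)")
print(f"  ΔΔG_mem = {dec.ddG_mem:+.2f} ± {dec.err_mem:.2f} kcal/mol  (membrane − water)")
print("\nΔΔG_obs = ΔΔG_int + ΔΔG_mem holds exactly; here roughly half of the "
      "affinity gain comes from membrane partitioning rather than specific "
      "protein contacts.")
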