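"""Forward calculation: C_TSP, OC0 and osmotic pressure of a solute mixture.

A glucose + NaCl + MgSO4 mixture faces a membrane that partially passes
NaCl (sigma = 0.5) and fully reflects everything else.  The script prints
the intrinsic particle concentration of the solution (C_TSP), the
membrane-dependent osmotically effective fraction (OC0) under both
sigma-application conventions, and the resulting van 't Hoff pressure.
"""

from osmocalc import (
    Membrane,
    SoluteMolecule,
    SolutionComposition,
    ThermodynamicContext,
    ctsp_ideal,
    ctsp_nonideal,
    electroneutrality_check,
    oc0_molecule_based,
    oc0_particle_based,
    osmotic_pressure,
)

glucose = SoluteMolecule.nonelectrolyte("glucose")
nacl = SoluteMolecule.electrolyte("NaCl", [("Na+", 1, 1), ("Cl-", -1, 1)], phi=0.93)
mgso4 = SoluteMolecule.electrolyte("MgSO4", [("Mg2+", 2, 1), ("SO4^2-", -2, 1)])

solution = SolutionComposition(((glucose, 0.005), (nacl, 0.140), (mgso4, 0.001)))
membrane = Membrane(
    sigma_by_molecule={"NaCl": 0.5},
    sigma_by_species={"Na+": 0.5, "Cl-": 0.5},
)
context = ThermodynamicContext(298.15, "bar")

print(f"C_TSP (ideal)      = {ctsp_ideal(solution):.4f} osmol/L")
print(f"C_TSP (with phi)   = {ctsp_nonideal(solution):.4f} osmol/L")
oc0_m = oc0_molecule_based(solution, membrane)
oc0_p = oc0_particle_based(solution, membrane)
print(f"OC0 (molecule law) = {oc0_m:.4f} osmol/L")
print(f"OC0 (particle law) = {oc0_p:.4f} osmol/L")
pi = osmotic_pressure(oc0_m, context)
print(f"pi = RT*OC0        = {pi.value:.3f} {pi.unit}")
print(f"electroneutrality  : {electroneutrality_check(solution, membrane).status}")
print()
print("C_TSP is a property of the solution alone; OC0 is smaller because the")
print("membrane lets half of the NaCl through, and pi is proportional to OC0.")
print("The particle-based figure differs: that convention omits phi by design.")
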