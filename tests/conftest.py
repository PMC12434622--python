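"""Shared fixtures and hypothesis strategies for random osmosis systems."""

from __future__ import annotations

import hypothesis
from hypothesis import strategies as st
import pytest

from osmocalc import (
    Membrane,
    SoluteMolecule,
    SolutionComposition,
    ThermodynamicContext,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

# small ion inventory for generated electrolytes
_IONS = [
    ("Na+", 1),
    ("K+", 1),
    ("Ca2+", 2),
    ("Mg2+", 2),
    ("Cl-", -1),
    ("SO4^2-", -2),
]

concentrations = st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False)
phis = st.floats(0.05, 1.0, exclude_min=True, allow_nan=False)
sigmas = st.floats(0.0, 1.0, allow_nan=False)


@st.composite
def molecules(draw, index: int = 0, phi=phis):
    """A random solute molecule: nonelectrolyte or 1:1/2:1 salt."""
    kind = draw(st.sampled_from(["nonelectrolyte", "salt_11", "salt_21"]))
    name = f"mol{index}_{kind}"
    phi_val = draw(phi)
    if kind == "nonelectrolyte":
        return SoluteMolecule.nonelectrolyte(name, phi_val)
    cat = draw(st.sampled_from([i for i in _IONS if i[1] > 0]))
    an = draw(st.sampled_from([i for i in _IONS if i[1] < 0]))
    if kind == "salt_11":
        ions = [(f"{name}:{cat[0]}", cat[1], 1), (f"{name}:{an[0]}", an[1], 1)]
    else:
        ions = [(f"{name}:{cat[0]}", cat[1], 1), (f"{name}:{an[0]}", an[1], 2)]
    return SoluteMolecule.electrolyte(name, ions, phi_val)


@st.composite
def solutions(draw, max_components: int = 4, phi=phis):
    n = draw(st.integers(0, max_components))
    comps = tuple(
        (draw(molecules(index=i, phi=phi)), draw(concentrations)) for i in range(n)
    )
    return SolutionComposition(comps)


@st.composite
def membranes_for(draw, solution: SolutionComposition, uniform_per_molecule=False):
    """A membrane with random per-molecule sigmas for the given solution.

    With ``uniform_per_molecule`` the same sigma is also assigned to each of
    the molecule's particle species, making methods 1 and 2 comparable.
    """
    by_mol: dict[str, float] = {}
    by_species: dict[str, float] = {}
    for mol, _ in solution.components:
        sigma = draw(sigmas)
        by_mol[mol.name] = sigma
        if uniform_per_molecule:
            for sp, _ in mol.stoichiometry:
                by_species[sp.name] = sigma
    return Membrane(by_species, by_mol, draw(sigmas))


contexts = st.builds(
    ThermodynamicContext,
    temperature=st.floats(250.0, 400.0),
    pressure_unit=st.sampled_from(["bar", "mmHg", "atm"]),
)


@pytest.fixture
def std_context() -> ThermodynamicContext:
    return ThermodynamicContext(298.15, "bar")


@pytest.fixture
def saline_mix() -> SolutionComposition:
    """glucose + NaCl + MgSO4 mix used across examples."""
    glucose = SoluteMolecule.nonelectrolyte("glucose")
    nacl = SoluteMolecule.electrolyte("NaCl", [("Na+", 1, 1), ("Cl-", -1, 1)])
    mgso4 = SoluteMolecule.electrolyte("MgSO4", [("Mg2+", 2, 1), ("SO4^2-", -2, 1)])
    return SolutionComposition(((glucose, 0.005), (nacl, 0.140), (mgso4, 0.001)))
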