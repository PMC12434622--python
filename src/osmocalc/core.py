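"""Domain types for solutes, solutions, membranes and thermodynamic context.

The central quantity is ``C_TSP``, the molar concentration of total solute
particles of a solution: ``sum_j g_j * C_j`` for an ideal solution, or
``sum_j g_j * Phi_j * C_j`` when per-molecule osmotic coefficients correct
for non-ideality.  ``C_TSP`` is an intrinsic property of the solution; the
membrane-dependent quantities (the osmotically effective fraction ``OC_0``)
live in :mod:`osmocalc.osmotics`.

Units are fixed internally: concentrations in mol/L (osmol/L for particle
totals), temperature in kelvin.  Milli-scale values (mM, mOsm/L), common in
physiology, are converted at I/O boundaries by a factor of 1000.

Complete dissociation is assumed throughout: a dissociable molecule with
dissociation number ``g`` contributes exactly ``g`` particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "ParticleSpecies",
    "SoluteMolecule",
    "SolutionComposition",
    "ParticleView",
    "Membrane",
    "ThermodynamicContext",
    "particle_view",
    "ctsp_ideal",
    "ctsp_nonideal",
    "resolve_phi",
    "GAS_CONSTANTS",
    "PRESSURE_UNITS",
]

#: Molar gas constant expressed in L·<unit>·mol⁻¹·K⁻¹ for each supported
#: pressure unit (CODATA R = 8.314462618 J mol⁻¹ K⁻¹).
GAS_CONSTANTS: Mapping[str, float] = {
    "bar": 0.08314462618,
    "mmHg": 62.363598,
    "atm": 0.0820573661,
}

PRESSURE_UNITS = tuple(GAS_CONSTANTS)


@dataclass(frozen=True)
class ParticleSpecies:
    """A solute-particle species: a non-dissociable molecule or a single ion.

    ``charge`` is in elementary-charge units, 0 for non-electrolytes.  It is
    carried so membrane-applicability checks on electroneutrality are
    computable; it enters no concentration or pressure formula.
    """

    name: str
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("particle species needs a non-empty name")


PhiTable = Sequence[tuple[float, float]]
PhiSpec = Union[float, PhiTable]


@dataclass(frozen=True)
class SoluteMolecule:
    """A solute type with dissociation number ``g`` and osmotic coefficient Φ.

    Parameters
    ----------
    name
        Unique identifier within a solution (e.g. ``"NaCl"``).
    dissociation_number
        ``g``, the count of particles released per molecule under complete
        dissociation (glucose 1, NaCl 2, CaCl2 3).
    stoichiometry
        Pairs ``(species, count)``; counts must sum to ``g``.  For a
        non-dissociable molecule (``g = 1``) the single species must carry
        the molecule's own name.
    phi_spec
        Either a constant Φ > 0, or a table of ``(concentration mol/L, Φ)``
        pairs with strictly increasing concentrations, resolved by
        piecewise-linear interpolation (no extrapolation).
    """

    name: str
    dissociation_number: int = 1
    stoichiometry: tuple[tuple[ParticleSpecies, int], ...] = ()
    phi_spec: PhiSpec = 1.0

    def __post_init__(self) -> None:
        g = self.dissociation_number
        if g < 1:
            raise ValueError(f"{self.name}: dissociation number must be >= 1, got {g}")
        stoich = tuple(self.stoichiometry)
        if not stoich:
            # default: the molecule itself is the single (neutral) particle
            stoich = ((ParticleSpecies(self.name, 0), g),)
        object.__setattr__(self, "stoichiometry", stoich)
        if any(count < 1 for _, count in stoich):
            raise ValueError(f"{self.name}: stoichiometric counts must be >= 1")
        total = sum(count for _, count in stoich)
        if total != g:
            raise ValueError(
                f"{self.name}: stoichiometry counts sum to {total}, expected g = {g}"
            )
        if g == 1:
            sp = stoich[0][0]
            if sp.name != self.name:
                raise ValueError(
                    f"{self.name}: a non-dissociable molecule is its own particle "
                    f"species (got {sp.name!r})"
                )
        if isinstance(self.phi_spec, (int, float)):
            if self.phi_spec <= 0:
                raise ValueError(f"{self.name}: constant phi must be > 0")
        else:
            table = tuple((float(c), float(p)) for c, p in self.phi_spec)
            if not table:
                raise ValueError(f"{self.name}: empty phi table")
            concs = [c for c, _ in table]
            if any(b <= a for a, b in zip(concs, concs[1:])):
                raise ValueError(f"{self.name}: phi table concentrations must increase")
            if any(p <= 0 for _, p in table):
                raise ValueError(f"{self.name}: phi values must be > 0")
            object.__setattr__(self, "phi_spec", table)

    @classmethod
    def nonelectrolyte(cls, name: str, phi: PhiSpec = 1.0) -> "SoluteMolecule":
        """A non-dissociable solute (g = 1), e.g. glucose, sucrose, urea."""
        return cls(name, 1, ((ParticleSpecies(name, 0), 1),), phi)

    @classmethod
    def electrolyte(
        cls,
        name: str,
        ions: Sequence[tuple[str, int, int]],
        phi: PhiSpec = 1.0,
    ) -> "SoluteMolecule":
        """A fully dissociating salt from ``(ion name, charge, count)`` triples.

        >>> nacl = SoluteMolecule.electrolyte("NaCl", [("Na+", 1, 1), ("Cl-", -1, 1)])
        >>> nacl.dissociation_number
        2
        """
        stoich = tuple((ParticleSpecies(n, z), k) for n, z, k in ions)
        g = sum(k for _, _, k in ions)
        return cls(name, g, stoich, phi)


@dataclass(frozen=True)
class SolutionComposition:
    """Per-molecule molar concentrations of one compartment.

    An empty composition is pure water and is legal everywhere (all derived
    concentrations and pressures are zero).
    """

    components: tuple[tuple[SoluteMolecule, float], ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        names = [m.name for m, _ in comps]
        if len(set(names)) != len(names):
            raise ValueError("duplicate molecule names in solution")
        for mol, conc in comps:
            if conc < 0:
                raise ValueError(f"{mol.name}: negative concentration {conc}")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[SoluteMolecule, float]]
    ) -> "SolutionComposition":
        return cls(tuple(pairs))

    def is_pure_water(self) -> bool:
        return all(c == 0 for _, c in self.components)

    def scaled(self, alpha: float) -> "SolutionComposition":
        """Same solutes at ``alpha``-fold concentration (alpha >= 0)."""
        if alpha < 0:
            raise ValueError("scale factor must be >= 0")
        return SolutionComposition(
            tuple((m, alpha * c) for m, c in self.components)
        )


@dataclass(frozen=True)
class ParticleView:
    """Mapping from particle species to molar concentration C_i (mol/L)."""

    entries: Mapping[ParticleSpecies, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.entries.values()))


@dataclass(frozen=True)
class Membrane:
    """Reflection coefficients σ defining the impermeant fraction of solutes.

    σ = 1 means the membrane is impermeable to that particle or molecule;
    σ = 0 means freely permeable.  Lookups fall back to ``default_sigma``,
    so ``Membrane()`` is the ideal membrane (water-permeable only).

    Maps are keyed by name; ``sigma_by_molecule`` applies σ to whole
    molecules (method 1), ``sigma_by_species`` to individual particles
    (method 2).
    """

    sigma_by_species: Mapping[str, float] = field(default_factory=dict)
    sigma_by_molecule: Mapping[str, float] = field(default_factory=dict)
    default_sigma: float = 1.0

    def __post_init__(self) -> None:
        for label, table in (
            ("species", self.sigma_by_species),
            ("molecule", self.sigma_by_molecule),
        ):
            for name, sigma in table.items():
                if not 0.0 <= sigma <= 1.0:
                    raise ValueError(f"sigma[{label} {name!r}] = {sigma} not in [0, 1]")
        if not 0.0 <= self.default_sigma <= 1.0:
            raise ValueError(f"default sigma {self.default_sigma} not in [0, 1]")

    def sigma_for_molecule(self, molecule: SoluteMolecule) -> float:
        return float(self.sigma_by_molecule.get(molecule.name, self.default_sigma))

    def sigma_for_species(self, species: ParticleSpecies) -> float:
        return float(self.sigma_by_species.get(species.name, self.default_sigma))


@dataclass(frozen=True)
class ThermodynamicContext:
    """Temperature and pressure-unit system supplying the RT factor.

    ``gas_constant`` defaults to the CODATA value expressed in
    L·<pressure_unit>·mol⁻¹·K⁻¹; pass an explicit value to reproduce
    published computations that used a rounded constant.
    """

    temperature: float = 298.15
    pressure_unit: str = "bar"
    gas_constant: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("absolute temperature must be > 0")
        if self.pressure_unit not in GAS_CONSTANTS:
            raise ValueError(
                f"unknown pressure unit {self.pressure_unit!r}; "
                f"expected one of {PRESSURE_UNITS}"
            )
        if self.gas_constant is None:
            object.__setattr__(
                self, "gas_constant", GAS_CONSTANTS[self.pressure_unit]
            )
        elif self.gas_constant <= 0:
            raise ValueError("gas constant must be > 0")

    @property
    def rt(self) -> float:
        """R·T in L·<pressure_unit>/mol."""
        return self.gas_constant * self.temperature


def resolve_phi(molecule: SoluteMolecule, concentration: float) -> float:
    """Resolve the osmotic coefficient Φ of ``molecule`` at a concentration.

    A constant spec returns its value.  A tabular spec is interpolated
    piecewise-linearly between bracketing rows; concentrations outside the
    table raise ``ValueError`` rather than silently extrapolating.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    spec = molecule.phi_spec
    if isinstance(spec, (int, float)):
        return float(spec)
    concs = np.array([c for c, _ in spec])
    phis = np.array([p for _, p in spec])
    if not concs[0] <= concentration <= concs[-1]:
        raise ValueError(
            f"{molecule.name}: concentration {concentration} outside phi table "
            f"range [{concs[0]}, {concs[-1]}]"
        )
    return float(np.interp(concentration, concs, phis))


def particle_view(solution: SolutionComposition) -> ParticleView:
    """Expand a solution to per-species particle concentrations.

    For each species, ``C_i = sum_j count_ij * C_j`` over molecules whose
    stoichiometry contains that species.
    """
    entries: dict[ParticleSpecies, float] = {}
    for mol, conc in solution.components:
        for species, count in mol.stoichiometry:
            entries[species] = entries.get(species, 0.0) + count * conc
    return ParticleView(entries)


def ctsp_ideal(solution: SolutionComposition) -> float:
    """Total-solute-particle concentration ``sum_j g_j * C_j`` (osmol/L)."""
    return float(
        sum(mol.dissociation_number * conc for mol, conc in solution.components)
    )


def ctsp_nonideal(solution: SolutionComposition) -> float:
    """Non-ideal ``C_TSP = sum_j g_j * Phi_j(C_j) * C_j`` (osmol/L).

    Reduces exactly to :func:`ctsp_ideal` when every Φ = 1.  Each molecule's
    Φ is resolved at that molecule's own concentration; cross-solute
    interactions and total-ionic-strength effects are outside this model.
    """
    return float(
        sum(
            mol.dissociation_number * resolve_phi(mol, conc) * conc
            for mol, conc in solution.components
        )
    )
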