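"""Simple, composite and complex osmosis systems.

A *simple* system is a solution facing pure water across a membrane
(S-m-H2O); its second compartment has zero osmotic concentration by
construction.  A *composite* system has solutions on both sides (S1-m-S2)
and deconstructs into two mirrored simple systems, S1-m-H2O and H2O-m-S2;
the pressure gradient is the (signed) sum of their opposing van 't Hoff
pressures, ``delta_pi = RT * (OC0_1 - OC0_2)``.

A *complex* system is one where some solutes permeate non-negligibly.  It
splits into an osmosis subsystem (the impermeant molecules, which generate
pressure) and a diffusion subsystem (the permeant molecules, which simply
equilibrate and are represented but not simulated — no flux model is
attached).

Sign convention: ``delta_pi > 0`` means net water movement toward
compartment 1 (the side with the larger OC₀); ``direction`` names the
receiving compartment explicitly.  The gradient is the t = 0 value computed
from initial concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .core import (
    Membrane,
    SoluteMolecule,
    SolutionComposition,
    ThermodynamicContext,
    ctsp_ideal,
)
from .osmotics import Method, SystemCoefficient, oc0, osmotic_pressure

__all__ = [
    "SimpleOsmosisSystem",
    "CompositeOsmosisSystem",
    "ComplexDecomposition",
    "GradientResult",
    "deconstruct_composite",
    "composite_gradient",
    "extended_gradient",
    "split_complex",
]

PURE_WATER = SolutionComposition()


@dataclass(frozen=True)
class SimpleOsmosisSystem:
    """S-m-H2O: one solution against pure water across a membrane."""

    solution: SolutionComposition
    membrane: Membrane
    context: ThermodynamicContext

    def oc0(self, method: Method = "molecule") -> float:
        return oc0(self.solution, self.membrane, method)

    def pressure(self, method: Method = "molecule"):
        return osmotic_pressure(self.oc0(method), self.context)


@dataclass(frozen=True)
class CompositeOsmosisSystem:
    """S1-m-S2: two solutions sharing one membrane and context."""

    solution_1: SolutionComposition
    membrane: Membrane
    solution_2: SolutionComposition
    context: ThermodynamicContext

    def swapped(self) -> "CompositeOsmosisSystem":
        return CompositeOsmosisSystem(
            self.solution_2, self.membrane, self.solution_1, self.context
        )


@dataclass(frozen=True)
class GradientResult:
    """Signed osmotic pressure gradient across a composite system.

    ``delta_pi = RT * (oc0_1 - oc0_2)`` in ``unit``; ``direction`` is the
    compartment water moves toward ("compartment_1", "compartment_2", or
    "none" at equality).
    """

    delta_pi: float
    unit: str
    direction: Literal["compartment_1", "compartment_2", "none"]
    oc0_1: float
    oc0_2: float


@dataclass(frozen=True)
class ComplexDecomposition:
    """Partition of a solution into osmosis and diffusion subsystems.

    Every molecule of the original solution appears in exactly one
    subsystem; ``cutoff_used`` records the σ threshold that classified
    them.  The diffusion subsystem is a passive inventory of the permeant
    components.
    """

    osmosis_subsystem: SimpleOsmosisSystem
    diffusion_subsystem: tuple[tuple[SoluteMolecule, float], ...]
    cutoff_used: float


def deconstruct_composite(
    system: CompositeOsmosisSystem,
) -> tuple[SimpleOsmosisSystem, SimpleOsmosisSystem]:
    """Mirror a composite system into (S1-m-H2O, H2O-m-S2).

    Both halves share the membrane and context; subtracting their pressures
    reproduces :func:`composite_gradient`.
    """
    return (
        SimpleOsmosisSystem(system.solution_1, system.membrane, system.context),
        SimpleOsmosisSystem(system.solution_2, system.membrane, system.context),
    )


def _direction(oc0_1: float, oc0_2: float) -> str:
    if oc0_1 > oc0_2:
        return "compartment_1"
    if oc0_2 > oc0_1:
        return "compartment_2"
    return "none"


def composite_gradient(
    system: CompositeOsmosisSystem, method: Method = "molecule"
) -> GradientResult:
    """t = 0 gradient ``delta_pi = RT * (OC0(S1) - OC0(S2))``."""
    s1, s2 = deconstruct_composite(system)
    oc0_1 = s1.oc0(method)
    oc0_2 = s2.oc0(method)
    delta = system.context.rt * (oc0_1 - oc0_2)
    return GradientResult(
        delta, system.context.pressure_unit, _direction(oc0_1, oc0_2), oc0_1, oc0_2
    )


def extended_gradient(
    system: CompositeOsmosisSystem, theta: SystemCoefficient
) -> GradientResult:
    """Extended-law gradient ``delta_pi = theta * (C_TSP_1 - C_TSP_2) * RT``.

    A single θ must apply to both compartments (caller-asserted; sensible
    when the two solutions are compositionally similar, e.g. body-fluid
    compartments).  C_TSP is the ideal total-particle sum Σ g·C — θ is the
    empirical correction, so folding per-molecule Φ in as well would count
    non-ideality twice.
    """
    c1 = theta.theta * ctsp_ideal(system.solution_1)
    c2 = theta.theta * ctsp_ideal(system.solution_2)
    delta = system.context.rt * (c1 - c2)
    return GradientResult(
        delta, system.context.pressure_unit, _direction(c1, c2), c1, c2
    )


def split_complex(
    solution: SolutionComposition,
    membrane: Membrane,
    sigma_cutoff: float = 0.95,
    context: ThermodynamicContext | None = None,
) -> ComplexDecomposition:
    """Split a solution into impermeant (osmosis) and permeant (diffusion) parts.

    Molecules with per-molecule σ >= ``sigma_cutoff`` form the osmosis
    subsystem (a simple system against pure water); the rest form the
    diffusion subsystem.  Classification is per molecule, keeping
    dissociated ion pairs together.  The default cutoff 0.95 treats only
    near-total reflection as osmotically effective; it is configurable
    because "negligible permeability" is application-dependent.
    """
    if not 0.0 < sigma_cutoff <= 1.0:
        raise ValueError(f"sigma cutoff must be in (0, 1], got {sigma_cutoff}")
    if context is None:
        context = ThermodynamicContext()
    retained: list[tuple[SoluteMolecule, float]] = []
    permeant: list[tuple[SoluteMolecule, float]] = []
    for mol, conc in solution.components:
        if membrane.sigma_for_molecule(mol) >= sigma_cutoff:
            retained.append((mol, conc))
        else:
            permeant.append((mol, conc))
    osmosis = SimpleOsmosisSystem(
        SolutionComposition(tuple(retained)), membrane, context
    )
    return ComplexDecomposition(osmosis, tuple(permeant), sigma_cutoff)
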