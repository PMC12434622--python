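"""Osmotically effective concentration OC₀ and van 't Hoff pressures.

OC₀ is the membrane-dependent, osmotically effective (impermeant) fraction
of a solution's total-particle concentration at t = 0 in a simple osmosis
system.  Two σ-application conventions are supported:

* molecule-based (method 1): ``OC0 = sum_j g_j * sigma_j * Phi_j * C_j`` —
  the reflection coefficient applies to the molecule as a whole, and the
  per-molecule osmotic coefficient is included.  Preferred when Φ is known.
* particle-based (method 2): ``OC0 = sum_i sigma_i * C_i`` over the particle
  view — σ applies per species and carries no Φ factor.

The unified pressure law is ``pi = RT * OC0``; the extended law
``pi = theta * C_TSP * RT`` replaces OC₀ with an empirically fitted
system coefficient θ times the intrinsic C_TSP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .core import (
    Membrane,
    SolutionComposition,
    ThermodynamicContext,
    ctsp_nonideal,
    particle_view,
    resolve_phi,
)

__all__ = [
    "PressureResult",
    "SystemCoefficient",
    "ElectroneutralityVerdict",
    "oc0",
    "oc0_molecule_based",
    "oc0_particle_based",
    "osmotic_pressure",
    "extended_pressure",
    "electroneutrality_check",
    "convert_pressure",
    "BAR_FACTORS",
]

Method = Literal["molecule", "particle"]

#: 1 bar expressed in each supported unit (exact: 1 atm = 101325 Pa,
#: 1 mmHg = 1 torr = 101325/760 Pa).
BAR_FACTORS = {
    "bar": 1.0,
    "mmHg": 1.0e5 * 760.0 / 101325.0,  # 750.0616827…
    "atm": 1.0e5 / 101325.0,  # 0.98692326…
}


@dataclass(frozen=True)
class PressureResult:
    """An osmotic pressure with the concentration and context that produced it."""

    value: float
    unit: str
    oc0: float
    context: ThermodynamicContext


@dataclass(frozen=True)
class SystemCoefficient:
    """The osmosis-system coefficient θ of the extended law π = θ·C_TSP·RT.

    θ is an emergent, system-level empirical factor — fitted from a measured
    pressure or a measured (corrected) osmolar activity, never derived from
    first principles.  θ = 1 recovers the ideal law.
    """

    theta: float
    source: Literal["fitted_from_pressure", "fitted_from_activity", "assumed"] = (
        "assumed"
    )

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass(frozen=True)
class ElectroneutralityVerdict:
    """Applicability verdict for per-species σ arithmetic.

    The σ-summation forms assume the membrane is exclusively impermeable to
    either all cations or all anions.  If charged species of both signs are
    permeant (σ < 1), paired diffusion keeps both compartments neutral and
    the formulas lose their meaning; this is surfaced as a WARN verdict, not
    an error, because it is an applicability criterion rather than a
    computational rule.
    """

    status: Literal["PASS", "WARN"]
    permeant_cations: tuple[str, ...] = ()
    permeant_anions: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.status == "PASS"


def oc0_molecule_based(solution: SolutionComposition, membrane: Membrane) -> float:
    """Method 1: ``OC0 = sum_j g_j * sigma_j * Phi_j(C_j) * C_j`` (osmol/L).

    Equals :func:`osmocalc.core.ctsp_nonideal` when every σ_j = 1.
    """
    return float(
        sum(
            mol.dissociation_number
            * membrane.sigma_for_molecule(mol)
            * resolve_phi(mol, conc)
            * conc
            for mol, conc in solution.components
        )
    )


def oc0_particle_based(solution: SolutionComposition, membrane: Membrane) -> float:
    """Method 2: ``OC0 = sum_i sigma_i * C_i`` over the particle view (osmol/L).

    Carries no Φ factor: the per-particle convention is defined for ideal
    solutions with non-ideal membranes.
    """
    view = particle_view(solution)
    return float(
        sum(
            membrane.sigma_for_species(species) * conc
            for species, conc in view.entries.items()
        )
    )


def oc0(
    solution: SolutionComposition,
    membrane: Membrane,
    method: Method = "molecule",
) -> float:
    """OC₀ by the chosen σ-application convention (default molecule-based)."""
    if method == "molecule":
        return oc0_molecule_based(solution, membrane)
    if method == "particle":
        return oc0_particle_based(solution, membrane)
    raise ValueError(f"unknown method {method!r}; expected 'molecule' or 'particle'")


def osmotic_pressure(oc0: float, context: ThermodynamicContext) -> PressureResult:
    """Unified van 't Hoff law ``pi = RT * OC0`` in the context's unit."""
    if oc0 < 0:
        raise ValueError(f"OC0 must be >= 0, got {oc0}")
    return PressureResult(context.rt * oc0, context.pressure_unit, oc0, context)


def extended_pressure(
    ctsp: float, theta: SystemCoefficient, context: ThermodynamicContext
) -> PressureResult:
    """Extended law ``pi = theta * C_TSP * RT``.

    ``theta.theta * ctsp`` plays the role of OC₀; with θ = 1 this is exactly
    ``osmotic_pressure(ctsp, context)``.
    """
    if ctsp < 0:
        raise ValueError(f"C_TSP must be >= 0, got {ctsp}")
    effective = theta.theta * ctsp
    return PressureResult(
        context.rt * effective, context.pressure_unit, effective, context
    )


def extended_pressure_of(
    solution: SolutionComposition,
    theta: SystemCoefficient,
    context: ThermodynamicContext,
) -> PressureResult:
    """Extended law applied to a solution's non-ideal C_TSP."""
    return extended_pressure(ctsp_nonideal(solution), theta, context)


def electroneutrality_check(
    solution: SolutionComposition, membrane: Membrane
) -> ElectroneutralityVerdict:
    """Check whether per-species σ summation is applicable to this system.

    PASS when every charged species with σ < 1 shares one charge sign (or no
    charged species is permeant at all); WARN otherwise, naming the permeant
    cations and anions.
    """
    view = particle_view(solution)
    cations: list[str] = []
    anions: list[str] = []
    for species in view.entries:
        if species.charge == 0:
            continue
        if membrane.sigma_for_species(species) < 1.0:
            (cations if species.charge > 0 else anions).append(species.name)
    if cations and anions:
        return ElectroneutralityVerdict("WARN", tuple(cations), tuple(anions))
    return ElectroneutralityVerdict("PASS", tuple(cations), tuple(anions))


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Exact-factor pressure conversion between bar, mmHg and atm."""
    for unit in (from_unit, to_unit):
        if unit not in BAR_FACTORS:
            raise ValueError(f"unknown pressure unit {unit!r}")
    return value / BAR_FACTORS[from_unit] * BAR_FACTORS[to_unit]
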