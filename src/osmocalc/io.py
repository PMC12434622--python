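"""File formats: CSV solute tables, JSON system specs, report writers.

Solute-table CSV
----------------
Header ``molecule,conc_mM,g,phi,sigma``; one molecule per row, with
concentrations in mM (the physiology convention) converted to mol/L on
read.  Empty ``phi`` defaults to 1; empty ``sigma`` falls back to the
membrane default.  A molecule row may be followed by 4-field species rows
``species,charge,count,sigma_i`` detailing its dissociation products; a
dissociable molecule without species rows gets a single neutral
pseudo-species ``<name>_particles`` carrying all g particles.

System spec (JSON)
------------------
``{"type": "simple"|"composite", "compartment1": {"solutes": [...]},
"compartment2": {...}, "membrane": {"default_sigma": ..,
"sigma_by_molecule": {..}, "sigma_by_species": {..}},
"temperature_K": .., "pressure_unit": ..}``.  ``compartment2`` may be
omitted (or ``type`` set to ``"simple"``) for a solution-vs-water system.
Each solute entry: ``{"name", "conc_mM", "g", "phi", "species":
[{"name", "charge", "count"}]}`` with ``g``, ``phi`` and ``species``
optional.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Any, Union

from .core import (
    Membrane,
    ParticleSpecies,
    PRESSURE_UNITS,
    SoluteMolecule,
    SolutionComposition,
    ThermodynamicContext,
)
from .inverse import ValidationReport
from .systems import CompositeOsmosisSystem, GradientResult, SimpleOsmosisSystem

__all__ = [
    "RunConfig",
    "InputError",
    "read_solute_table",
    "read_system_spec",
    "parse_system_spec",
    "system_spec_to_dict",
    "write_report",
]

MM_PER_MOLAR = 1000.0


class InputError(ValueError):
    """Malformed input file; message carries the offending row or key."""


@dataclass(frozen=True)
class RunConfig:
    """Run-wide defaults for the CLI and report writers."""

    method: str = "molecule"
    pressure_unit: str = "bar"
    temperature: float = 298.15
    sigma_cutoff: float = 0.95
    rounding_profile: str = "none"  # none | sucrose | body_fluids
    log_level: str = "WARNING"


def _parse_float(text: str, what: str, row: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise InputError(f"row {row}: cannot parse {what} from {text!r}") from None


def _build_molecule(
    name: str,
    g: int,
    phi: float,
    species_rows: list[tuple[str, int, int]],
) -> SoluteMolecule:
    if species_rows:
        stoich = tuple(
            (ParticleSpecies(sp_name, charge), count)
            for sp_name, charge, count in species_rows
        )
        return SoluteMolecule(name, g, stoich, phi)
    if g == 1:
        return SoluteMolecule.nonelectrolyte(name, phi)
    # no per-ion detail given: one neutral pseudo-species carries all g particles
    return SoluteMolecule(
        name, g, ((ParticleSpecies(f"{name}_particles", 0), g),), phi
    )


def read_solute_table(path: Union[str, Path]) -> tuple[SolutionComposition, Membrane]:
    """Parse a solute-table CSV into a composition and a membrane."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and any(cell.strip() for cell in r)]
    if not rows:
        raise InputError(f"{path}: empty file")
    header = [c.strip().lower() for c in rows[0]]
    if header[:5] != ["molecule", "conc_mm", "g", "phi", "sigma"]:
        raise InputError(
            f"{path}: expected header 'molecule,conc_mM,g,phi,sigma', got {rows[0]!r}"
        )

    components: list[tuple[SoluteMolecule, float]] = []
    sigma_by_molecule: dict[str, float] = {}
    sigma_by_species: dict[str, float] = {}
    pending: dict[str, Any] | None = None

    def flush() -> None:
        nonlocal pending
        if pending is None:
            return
        mol = _build_molecule(
            pending["name"], pending["g"], pending["phi"], pending["species"]
        )
        components.append((mol, pending["conc"]))
        pending = None

    for idx, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        if len(cells) == 4:  # species row attached to the previous molecule
            if pending is None:
                raise InputError(f"row {idx}: species row without a preceding molecule")
            sp_name = cells[0]
            charge = int(_parse_float(cells[1], "charge", idx))
            count = int(_parse_float(cells[2], "count", idx))
            if count < 1:
                raise InputError(f"row {idx}: species count must be >= 1")
            pending["species"].append((sp_name, charge, count))
            if cells[3]:
                sigma_i = _parse_float(cells[3], "sigma_i", idx)
                if not 0.0 <= sigma_i <= 1.0:
                    raise InputError(f"row {idx}: sigma_i {sigma_i} not in [0, 1]")
                sigma_by_species[sp_name] = sigma_i
            continue
        if len(cells) != 5:
            raise InputError(f"row {idx}: expected 5 (molecule) or 4 (species) fields")
        flush()
        name = cells[0]
        if not name:
            raise InputError(f"row {idx}: missing molecule name")
        conc_mm = _parse_float(cells[1], "conc_mM", idx)
        if conc_mm < 0:
            raise InputError(f"row {idx}: negative concentration for {name!r}")
        g = int(_parse_float(cells[2], "g", idx)) if cells[2] else 1
        if g < 1:
            raise InputError(f"row {idx}: g must be >= 1 for {name!r}")
        phi = _parse_float(cells[3], "phi", idx) if cells[3] else 1.0
        if cells[4]:
            sigma = _parse_float(cells[4], "sigma", idx)
            if not 0.0 <= sigma <= 1.0:
                raise InputError(f"row {idx}: sigma {sigma} not in [0, 1] for {name!r}")
            sigma_by_molecule[name] = sigma
        pending = {
            "name": name,
            "conc": conc_mm / MM_PER_MOLAR,
            "g": g,
            "phi": phi,
            "species": [],
        }
    flush()
    return (
        SolutionComposition(tuple(components)),
        Membrane(sigma_by_species, sigma_by_molecule),
    )


def _solutes_from_spec(entries: list[dict], where: str) -> SolutionComposition:
    comps: list[tuple[SoluteMolecule, float]] = []
    for i, entry in enumerate(entries):
        try:
            name = entry["name"]
            conc = float(entry["conc_mM"]) / MM_PER_MOLAR
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"{where}[{i}]: {exc}") from None
        g = int(entry.get("g", 1))
        phi = entry.get("phi", 1.0)
        species = [
            (sp["name"], int(sp.get("charge", 0)), int(sp.get("count", 1)))
            for sp in entry.get("species", [])
        ]
        try:
            mol = _build_molecule(name, g, phi, species)
            comps.append((mol, conc))
        except ValueError as exc:
            raise InputError(f"{where}[{i}]: {exc}") from None
    try:
        return SolutionComposition(tuple(comps))
    except ValueError as exc:
        raise InputError(f"{where}: {exc}") from None


def parse_system_spec(
    spec: dict,
) -> Union[SimpleOsmosisSystem, CompositeOsmosisSystem]:
    """Build an osmosis system from an already-decoded spec dictionary."""
    kind = spec.get("type")
    if kind is None:
        kind = "composite" if "compartment2" in spec else "simple"
    if kind not in ("simple", "composite"):
        raise InputError(f"unknown system type {kind!r}")
    unit = spec.get("pressure_unit", "bar")
    if unit not in PRESSURE_UNITS:
        raise InputError(f"unknown pressure unit {unit!r}")
    try:
        context = ThermodynamicContext(float(spec.get("temperature_K", 298.15)), unit)
    except ValueError as exc:
        raise InputError(str(exc)) from None
    mspec = spec.get("membrane", {})
    try:
        membrane = Membrane(
            dict(mspec.get("sigma_by_species", {})),
            dict(mspec.get("sigma_by_molecule", {})),
            float(mspec.get("default_sigma", 1.0)),
        )
    except ValueError as exc:
        raise InputError(f"membrane: {exc}") from None
    s1 = _solutes_from_spec(
        spec.get("compartment1", {}).get("solutes", []), "compartment1"
    )
    if kind == "simple":
        return SimpleOsmosisSystem(s1, membrane, context)
    s2 = _solutes_from_spec(
        spec.get("compartment2", {}).get("solutes", []), "compartment2"
    )
    return CompositeOsmosisSystem(s1, membrane, s2, context)


def read_system_spec(
    path: Union[str, Path],
) -> Union[SimpleOsmosisSystem, CompositeOsmosisSystem]:
    path = Path(path)
    try:
        spec = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(spec, dict):
        raise InputError(f"{path}: top-level spec must be an object")
    return parse_system_spec(spec)


def _solution_to_entries(solution: SolutionComposition) -> list[dict]:
    entries = []
    for mol, conc in solution.components:
        entry: dict[str, Any] = {
            "name": mol.name,
            "conc_mM": conc * MM_PER_MOLAR,
            "g": mol.dissociation_number,
        }
        if isinstance(mol.phi_spec, (int, float)):
            entry["phi"] = mol.phi_spec
        else:
            entry["phi"] = [list(pair) for pair in mol.phi_spec]
        if not (
            mol.dissociation_number == 1
            and mol.stoichiometry[0][0].name == mol.name
        ):
            entry["species"] = [
                {"name": sp.name, "charge": sp.charge, "count": count}
                for sp, count in mol.stoichiometry
            ]
        entries.append(entry)
    return entries


def system_spec_to_dict(
    system: Union[SimpleOsmosisSystem, CompositeOsmosisSystem],
) -> dict:
    """Serialize a system to the JSON-compatible spec schema (round-trips)."""
    membrane = system.membrane
    spec: dict[str, Any] = {
        "type": "simple" if isinstance(system, SimpleOsmosisSystem) else "composite",
        "temperature_K": system.context.temperature,
        "pressure_unit": system.context.pressure_unit,
        "membrane": {
            "default_sigma": membrane.default_sigma,
            "sigma_by_molecule": dict(membrane.sigma_by_molecule),
            "sigma_by_species": dict(membrane.sigma_by_species),
        },
    }
    if isinstance(system, SimpleOsmosisSystem):
        spec["compartment1"] = {"solutes": _solution_to_entries(system.solution)}
    else:
        spec["compartment1"] = {"solutes": _solution_to_entries(system.solution_1)}
        spec["compartment2"] = {"solutes": _solution_to_entries(system.solution_2)}
    return spec


def _report_payload(result: Any) -> dict:
    if isinstance(result, ValidationReport):
        return {
            "dataset": result.dataset,
            "passed": result.passed,
            "notes": list(result.notes),
            "cells": [asdict(c) | {"ok": c.ok} for c in result.cells],
        }
    if isinstance(result, GradientResult):
        return asdict(result)
    if is_dataclass(result) and not isinstance(result, type):
        return asdict(result)
    if isinstance(result, dict):
        return result
    raise TypeError(f"cannot serialize report for {type(result).__name__}")


def write_report(result: Any, format: str = "text") -> str:
    """Render a result deterministically as text, TSV, or JSON."""
    payload = _report_payload(result)
    if format == "json":
        return json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    if format == "delimited":
        if "cells" in payload:
            lines = ["\t".join(["row", "quantity", "expected", "computed", "ok"])]
            for cell in payload["cells"]:
                lines.append(
                    "\t".join(
                        str(cell[k])
                        for k in ("row", "quantity", "expected", "computed", "ok")
                    )
                )
            return "\n".join(lines) + "\n"
        lines = ["\t".join(str(k) for k in payload)]
        lines.append("\t".join(str(v) for v in payload.values()))
        return "\n".join(lines) + "\n"
    if format == "text":
        if "cells" in payload:
            lines = [f"dataset: {payload['dataset']}  passed: {payload['passed']}"]
            for cell in payload["cells"]:
                mark = "ok" if cell["ok"] else "MISMATCH"
                if cell["known_discrepancy"]:
                    mark = "known-discrepancy"
                lines.append(
                    f"  {cell['row']:>16s} {cell['quantity']:>9s} "
                    f"expected={cell['expected']!s:>8s} "
                    f"computed={cell['computed']!s:>8s} [{mark}]"
                )
            for note in payload.get("notes", []):
                lines.append(f"  note: {note}")
            return "\n".join(lines) + "\n"
        return "\n".join(f"{k}: {v}" for k, v in payload.items()) + "\n"
    raise ValueError(f"unknown report format {format!r}")
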