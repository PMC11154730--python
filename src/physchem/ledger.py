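"""Species-ledger data model and I/O.

The ledger is the contract between upstream electronic-structure work and
this pipeline: a YAML document per molecule holding, per phase, the summary
quantities every downstream property needs (total electronic energy, ZPVE
and thermal enthalpy correction in Hartree; Gibbs energies in kJ·mol⁻¹;
harmonic wavenumbers in cm⁻¹; frontier-orbital and vertical ionic-state
energies in eV; molecular-surface descriptors).  Nothing in the package runs
a quantum-chemistry engine — the ledger is read, validated and consumed.

Unit conventions follow the field declarations on :class:`QCRecord`;
``assemble_enthalpy`` is the only place the Hartree→kJ·mol⁻¹ factor is
applied to species enthalpies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml

from .constants import HARTREE_TO_KJMOL
from .phase_transfer import SurfaceDescriptors

PHASES = ("gas", "aqueous", "octanol", "lipid")

SCHEMA_VERSION = 1

#: Per-phase numeric fields copied verbatim from ledger documents.
_PHASE_FIELDS = (
    "electronic_energy",
    "zpve",
    "thermal_enthalpy_correction",
    "gibbs_energy",
    "frequencies",
    "rotational_constants",
    "homo_energy",
    "lumo_energy",
    "ground_energy",
    "vertical_cation_energy",
    "vertical_anion_energy",
    "dipole",
)


class LedgerError(ValueError):
    """Malformed or inconsistent ledger content."""


@dataclass
class QCRecord:
    """Quantum-chemistry summary record for one species in one phase.

    Energies: ``electronic_energy``, ``zpve`` and
    ``thermal_enthalpy_correction`` are in Hartree (electronic-structure
    boundary); ``gibbs_energy`` is in kJ·mol⁻¹; orbital and vertical
    ionic-state energies are in eV.  ``frequencies`` are harmonic
    wavenumbers in cm⁻¹, ``rotational_constants`` in GHz, ``molar_mass`` in
    g·mol⁻¹ and ``dipole`` in Debye.
    """

    species_id: str
    phase: str
    formula: str | None = None
    smiles: str | None = None
    molar_mass: float | None = None
    electronic_energy: float | None = None
    zpve: float | None = None
    thermal_enthalpy_correction: float | None = None
    gibbs_energy: float | None = None
    frequencies: list[float] | None = None
    rotational_constants: list[float] | None = None
    homo_energy: float | None = None
    lumo_energy: float | None = None
    ground_energy: float | None = None
    vertical_cation_energy: float | None = None
    vertical_anion_energy: float | None = None
    dipole: float | None = None
    surface_descriptors: SurfaceDescriptors | None = None
    extra: dict[str, Any] = field(default_factory=dict)
    validation_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise LedgerError(
                f"species {self.species_id!r}: unknown phase {self.phase!r}; "
                f"expected one of {PHASES}"
            )
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise LedgerError(f"species {self.species_id!r}: molar_mass must be > 0")
        if (
            self.homo_energy is not None
            and self.lumo_energy is not None
            and not self.homo_energy < self.lumo_energy
        ):
            raise LedgerError(
                f"species {self.species_id!r}: homo_energy must lie below lumo_energy"
            )
        if self.frequencies is not None and any(nu < 0 for nu in self.frequencies):
            # Not fatal: a failed optimization (imaginary mode) must be
            # representable so that validation can be tested downstream.
            self.validation_warnings.append(
                "imaginary mode present (negative wavenumber); not a confirmed minimum"
            )


def assemble_enthalpy(record: QCRecord) -> float:
    """Standard enthalpy of a species, kJ·mol⁻¹.

    Sum of the electronic energy, the zero-point vibrational energy and the
    thermal enthalpy correction (all Hartree), converted to kJ·mol⁻¹ in one
    multiplication so the assembly is exactly linear in each term.
    """
    missing = [
        name
        for name in ("electronic_energy", "zpve", "thermal_enthalpy_correction")
        if getattr(record, name) is None
    ]
    if missing:
        raise LedgerError(
            f"species {record.species_id!r} ({record.phase}): cannot assemble "
            f"enthalpy, missing field(s): {', '.join(missing)}"
        )
    total_hartree = (
        record.electronic_energy + record.zpve + record.thermal_enthalpy_correction
    )
    return total_hartree * HARTREE_TO_KJMOL


# --- file I/O ----------------------------------------------------------------


def _phase_block_to_record(
    species_doc: dict[str, Any], phase: str, block: dict[str, Any]
) -> QCRecord:
    known = {k: block[k] for k in _PHASE_FIELDS if k in block}
    sd = block.get("surface_descriptors")
    descriptors = SurfaceDescriptors(**sd) if sd is not None else None
    extra = {
        k: v
        for k, v in block.items()
        if k not in _PHASE_FIELDS and k != "surface_descriptors"
    }
    return QCRecord(
        species_id=species_doc["species_id"],
        phase=phase,
        formula=species_doc.get("formula"),
        smiles=species_doc.get("smiles"),
        molar_mass=species_doc.get("molar_mass"),
        surface_descriptors=descriptors,
        extra=extra,
        **known,
    )


def read_ledger(path: str | Path) -> list[QCRecord]:
    """Read a ledger file into one :class:`QCRecord` per (species, phase).

    An empty file yields an empty list.  Structural problems raise
    :class:`LedgerError` naming the offending species/field; a negative
    wavenumber is recorded as a validation warning on the record instead.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise LedgerError(f"{path}: not parseable as YAML: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc:
        raise LedgerError(f"{path}: missing top-level 'species' list")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise LedgerError(
            f"{path}: schema_version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    records: list[QCRecord] = []
    for i, species_doc in enumerate(doc["species"]):
        if "species_id" not in species_doc:
            raise LedgerError(f"{path}: species entry #{i} lacks 'species_id'")
        phases = species_doc.get("phases")
        if not isinstance(phases, dict) or not phases:
            raise LedgerError(
                f"{path}: species {species_doc['species_id']!r} lacks a 'phases' block"
            )
        for phase, block in phases.items():
            try:
                records.append(
                    _phase_block_to_record(species_doc, phase, block or {})
                )
            except TypeError as exc:
                raise LedgerError(
                    f"{path}: species {species_doc['species_id']!r}, phase "
                    f"{phase!r}: {exc}"
                ) from exc
    return records


def _plain(value: Any) -> Any:
    """Coerce numpy scalars/arrays to built-in types for clean YAML output."""
    import numpy as np

    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.ndarray):
        return [_plain(v) for v in value.tolist()]
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    return value


def write_ledger(records: Iterable[QCRecord], path: str | Path) -> None:
    """Write records back to the ledger format; inverse of :func:`read_ledger`."""
    by_species: dict[str, dict[str, Any]] = {}
    order: list[str] = []
    for rec in records:
        if rec.species_id not in by_species:
            order.append(rec.species_id)
            by_species[rec.species_id] = {
                "species_id": rec.species_id,
                **({"formula": rec.formula} if rec.formula is not None else {}),
                **({"smiles": rec.smiles} if rec.smiles is not None else {}),
                **({"molar_mass": rec.molar_mass} if rec.molar_mass is not None else {}),
                "phases": {},
            }
        block: dict[str, Any] = {}
        for name in _PHASE_FIELDS:
            value = getattr(rec, name)
            if value is not None:
                block[name] = _plain(value)
        if rec.surface_descriptors is not None:
            sd = rec.surface_descriptors
            block["surface_descriptors"] = {
                "surface_area": sd.surface_area,
                "sigma_tot_sq": sd.sigma_tot_sq,
                "nu": sd.nu,
            }
        block.update(_plain(rec.extra))
        by_species[rec.species_id]["phases"][rec.phase] = block
    doc = {
        "schema_version": SCHEMA_VERSION,
        "species": [by_species[sid] for sid in order],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def records_for(
    records: Sequence[QCRecord], species_id: str, phase: str | None = None
) -> list[QCRecord]:
    """Select records by species id and optionally phase."""
    out = [
        r
        for r in records
        if r.species_id == species_id and (phase is None or r.phase == phase)
    ]
    return out


def record_for(records: Sequence[QCRecord], species_id: str, phase: str) -> QCRecord:
    """The unique record for (species, phase); raises if absent."""
    matches = records_for(records, species_id, phase)
    if not matches:
        raise LedgerError(f"no record for species {species_id!r} in phase {phase!r}")
    return matches[0]
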