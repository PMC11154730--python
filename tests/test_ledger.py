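"""Ledger I/O, unit conversion and species-enthalpy assembly."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physchem.constants import HARTREE_TO_KJMOL, convert_energy
from physchem.ledger import (
    LedgerError,
    QCRecord,
    assemble_enthalpy,
    read_ledger,
    write_ledger,
)


@pytest.mark.parametrize(
    "value, src, dst, expected",
    [
        (1.0, "hartree", "kj/mol", 2625.4996),
        (0.0, "ev", "hartree", 0.0),
        (-0.5, "hartree", "kj/mol", -1312.7498),
        (1.0, "ev", "kj/mol", 96.485),
    ],
)
def test_convert_energy_known_factors(value, src, dst, expected):
    assert convert_energy(value, src, dst) == pytest.approx(expected, rel=1e-12)


def test_convert_energy_rejects_unknown_unit():
    with pytest.raises(ValueError):
        convert_energy(1.0, "hartree", "J/K/mol")


@given(st.floats(-1e4, 1e4), st.sampled_from(["hartree", "kj/mol", "ev", "kcal/mol"]),
       st.sampled_from(["hartree", "kj/mol", "ev", "kcal/mol"]))
@settings(max_examples=50, derandomize=True)
def test_convert_energy_composes_to_identity(value, a, b):
    assert convert_energy(convert_energy(value, a, b), b, a) == pytest.approx(
        value, rel=1e-12, abs=1e-12
    )


@pytest.mark.parametrize(
    "e, zpve_h, hcorr, expected",
    [
        (-1.0, 0.5, 0.5, 0.0),
        (-1.0, 0.0, 0.0, -2625.4996),
        (-540.0, 0.19, 0.01, -539.8 * 2625.4996),
    ],
)
def test_assemble_enthalpy(e, zpve_h, hcorr, expected):
    rec = QCRecord(
        "x", "gas", electronic_energy=e, zpve=zpve_h, thermal_enthalpy_correction=hcorr
    )
    assert assemble_enthalpy(rec) == pytest.approx(expected, abs=1e-9)


def test_assemble_enthalpy_names_missing_field():
    rec = QCRecord("x", "gas", electronic_energy=-1.0, zpve=0.1)
    with pytest.raises(LedgerError, match="thermal_enthalpy_correction"):
        assemble_enthalpy(rec)


def test_assemble_enthalpy_linear_in_electronic_energy():
    base = QCRecord("x", "gas", electronic_energy=-2.0, zpve=0.1,
                    thermal_enthalpy_correction=0.01)
    shifted = QCRecord("x", "gas", electronic_energy=-2.0 + 1e-3, zpve=0.1,
                       thermal_enthalpy_correction=0.01)
    delta = assemble_enthalpy(shifted) - assemble_enthalpy(base)
    assert delta == pytest.approx(1e-3 * HARTREE_TO_KJMOL, rel=1e-9)


def test_one_species_two_phases_gives_two_records(tmp_path):
    records = [
        QCRecord("mol", "gas", gibbs_energy=-1.0),
        QCRecord("mol", "aqueous", gibbs_energy=-2.0),
    ]
    path = tmp_path / "ledger.yaml"
    write_ledger(records, path)
    assert len(read_ledger(path)) == 2


def test_empty_file_gives_empty_collection(tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    assert read_ledger(path) == []


def test_round_trip_preserves_every_field(tmp_path, rk_fixture):
    path1, path2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
    write_ledger(rk_fixture.records, path1)
    back = read_ledger(path1)
    write_ledger(back, path2)
    assert path1.read_bytes() == path2.read_bytes()
    # records come back grouped by species; compare by (species, phase) key
    by_key = {(r.species_id, r.phase): r for r in back}
    assert len(by_key) == len(rk_fixture.records)
    for orig in rk_fixture.records:
        rec = by_key[(orig.species_id, orig.phase)]
        assert orig.gibbs_energy == rec.gibbs_energy
        assert orig.electronic_energy == rec.electronic_energy
        assert (orig.frequencies or []) == (rec.frequencies or [])
        assert orig.surface_descriptors == rec.surface_descriptors


def test_unknown_fields_survive_round_trip(tmp_path):
    rec = QCRecord("mol", "gas", gibbs_energy=-1.0, extra={"custom_tag": "hello"})
    path = tmp_path / "ledger.yaml"
    write_ledger([rec], path)
    assert read_ledger(path)[0].extra == {"custom_tag": "hello"}


def test_negative_frequency_flags_warning_not_error():
    rec = QCRecord("mol", "gas", frequencies=[-50.0, 100.0])
    assert rec.validation_warnings and "imaginary" in rec.validation_warnings[0]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(phase="plasma"),
        dict(phase="gas", molar_mass=-1.0),
        dict(phase="gas", homo_energy=0.5, lumo_energy=-0.5),
    ],
)
def test_invariant_violations_raise(kwargs):
    with pytest.raises(LedgerError):
        QCRecord("mol", **kwargs)


def test_malformed_file_names_problem(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("schema_version: 1\nspecies:\n  - phases: {gas: {}}\n")
    with pytest.raises(LedgerError, match="species_id"):
        read_ledger(path)
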