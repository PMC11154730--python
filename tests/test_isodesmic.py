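"""Isodesmic schemes: balance, bond inventories, Hess's law, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physchem.isodesmic import (
    SchemeError,
    aggregate_formation,
    bond_inventory,
    check_isodesmic,
    formation_enthalpy,
    load_reference_table,
    parse_formula,
    parse_reaction,
    reaction_enthalpy,
)


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("CH4", {"C": 1, "H": 4}),
        ("C10H12O2", {"C": 10, "H": 12, "O": 2}),
        ("CH3(CH2)2OH", {"C": 3, "H": 8, "O": 1}),
    ],
)
def test_parse_formula(formula, expected):
    assert dict(parse_formula(formula)) == expected


def test_parse_reaction_identity_scheme():
    scheme = parse_reaction("A + B = A + B", {"A": "CH4", "B": "H2O"})
    assert scheme.reactants == scheme.products == {"A": 1, "B": 1}


def test_parse_reaction_accepts_balanced_formulas():
    scheme = parse_reaction("C10H12O2 + CH4 = C7H8O + C4H8O")
    assert scheme.products == {"C7H8O": 1, "C4H8O": 1}


def test_parse_reaction_reports_element_deficit():
    with pytest.raises(SchemeError, match="C"):
        parse_reaction("C10H12O2 + CH4 = C7H8 + C5H10O2")


@pytest.mark.parametrize(
    "smiles, expected",
    [
        ("C", {("C", "H", 1.0, False): 4}),
        (
            "CCO",
            {
                ("C", "C", 1.0, False): 1,
                ("C", "O", 1.0, False): 1,
                ("H", "O", 1.0, False): 1,
                ("C", "H", 1.0, False): 5,
            },
        ),
        (
            "c1ccccc1",
            {("C", "C", 1.5, True): 6, ("C", "H", 1.0, False): 6},
        ),
    ],
)
def test_bond_inventory_hand_counts(smiles, expected):
    assert dict(bond_inventory(smiles)) == expected


def test_bond_inventory_rejects_garbage():
    with pytest.raises(SchemeError):
        bond_inventory("not-a-smiles(((")


def test_check_isodesmic_identity_scheme():
    scheme = parse_reaction("A = A", {"A": "CH4"})
    ok, table = check_isodesmic(scheme, {"A": bond_inventory("C")})
    assert ok and all(v == 0 for v in table.values())


def test_check_isodesmic_metathesis_true():
    formulas = {"ethanol": "C2H6O", "methane": "CH4", "methanol": "CH4O", "ethane": "C2H6"}
    inv = {
        "ethanol": bond_inventory("CCO"),
        "methane": bond_inventory("C"),
        "methanol": bond_inventory("CO"),
        "ethane": bond_inventory("CC"),
    }
    scheme = parse_reaction("ethanol + methane = methanol + ethane", formulas)
    ok, _ = check_isodesmic(scheme, inv)
    assert ok


def test_check_isodesmic_hydrogenation_false():
    formulas = {"ethene": "C2H4", "h2": "H2", "ethane": "C2H6"}
    inv = {
        "ethene": bond_inventory("C=C"),
        "h2": bond_inventory("[H][H]"),
        "ethane": bond_inventory("CC"),
    }
    scheme = parse_reaction("ethene + h2 = ethane", formulas)
    ok, table = check_isodesmic(scheme, inv)
    assert not ok
    assert table[("C", "C", 2.0, False)] == -1  # the C=C that disappears


def test_rk_schemes_are_isodesmic(rk_fixture):
    inv = {
        rec.species_id: bond_inventory(rec.smiles)
        for rec in rk_fixture.records
        if rec.phase == "gas" and rec.smiles and rec.electronic_energy is not None
    }
    for scheme in rk_fixture.schemes:
        ok, table = check_isodesmic(scheme, inv)
        assert ok, f"{scheme.label}: {table}"


def test_reaction_enthalpy_identity_and_linearity():
    scheme = parse_reaction("A = A", {"A": "CH4"})
    assert reaction_enthalpy(scheme, {"A": -123.4}) == 0.0
    formulas = {"a": "CH4", "b": "H2O", "c": "CH4O", "d": "H2"}
    h = {"a": -100.0, "b": -250.0, "c": -300.0, "d": 10.0}
    single = parse_reaction("a + b = c + d", formulas)
    double = parse_reaction("2 a + 2 b = 2 c + 2 d", formulas)
    assert reaction_enthalpy(double, h) == pytest.approx(
        2 * reaction_enthalpy(single, h), rel=1e-14
    )
    assert reaction_enthalpy(single.reversed(), h) == pytest.approx(
        -reaction_enthalpy(single, h), rel=1e-14
    )


def test_rk_fixture_reproduces_scheme_one(rk_fixture):
    from physchem.ledger import assemble_enthalpy

    enthalpies = {
        rec.species_id: assemble_enthalpy(rec)
        for rec in rk_fixture.records
        if rec.phase == "gas" and rec.electronic_energy is not None
    }
    scheme = rk_fixture.schemes[0]
    assert reaction_enthalpy(scheme, enthalpies) == pytest.approx(11.54, abs=0.01)


def test_formation_enthalpy_hess_example():
    formulas = {"A": "CH4O", "B": "H2O", "C": "CH4", "D": "O2H2"}
    scheme = parse_reaction("A + B = C + D", formulas)
    refs = {"B": (-75.0, 0.0), "C": (-100.0, 0.0), "D": (-150.0, 0.0)}
    est = formation_enthalpy(scheme, 10.0, refs)
    assert est.delta_f_h == pytest.approx(-185.0, rel=1e-12)


def test_formation_enthalpy_zero_case_and_two_unknowns():
    formulas = {"A": "CH4O", "B": "H2O", "C": "CH4", "D": "O2H2"}
    scheme = parse_reaction("A + B = C + D", formulas)
    refs0 = {"B": (0.0, 0.0), "C": (0.0, 0.0), "D": (0.0, 0.0)}
    assert formation_enthalpy(scheme, 0.0, refs0).delta_f_h == 0.0
    with pytest.raises(SchemeError, match="exactly one"):
        formation_enthalpy(scheme, 0.0, {"B": (0.0, 0.0), "C": (0.0, 0.0)})


def test_rk_scheme_one_formation_matches_reference_budget(rk_fixture):
    refs = load_reference_table()
    est = formation_enthalpy(rk_fixture.schemes[0], 11.54, refs)
    assert est.delta_f_h == pytest.approx(-300.8, abs=est.uncertainty)
    assert est.uncertainty == pytest.approx(1.57, abs=0.005)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_formation_round_trip_recovers_target(seed):
    """Consistent enthalpies built from random references + a random target
    must solve back to the target exactly (Hess-law round trip)."""
    rng = np.random.default_rng(seed)
    formulas = {"T": "C10H12O2", "m": "CH4", "p": "C7H8O", "k": "C4H8O"}
    scheme = parse_reaction("T + m = p + k", formulas)
    refs = {s: (float(rng.uniform(-400, 100)), float(rng.uniform(0, 2)))
            for s in ("m", "p", "k")}
    target = float(rng.uniform(-400, 100))
    mu = {el: float(rng.uniform(-1e5, -1e4)) for el in ("C", "H", "O")}

    def enthalpy(species, dfh):
        return dfh + sum(n * mu[el] for el, n in parse_formula(formulas[species]).items())

    h = {s: enthalpy(s, refs[s][0]) for s in refs}
    h["T"] = enthalpy("T", target)
    est = formation_enthalpy(scheme, reaction_enthalpy(scheme, h), refs)
    assert est.delta_f_h == pytest.approx(target, abs=1e-6)


def test_aggregate_formation_edge_cases():
    from physchem.isodesmic import FormationEstimate

    one = [FormationEstimate("a", 0.0, -10.0, 0.1)]
    mean, ci, _ = aggregate_formation(one)
    assert mean == -10.0 and math.isnan(ci)
    two = one + [FormationEstimate("b", 0.0, -10.0, 0.1)]
    mean, ci, _ = aggregate_formation(two)
    assert mean == -10.0 and ci == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(SchemeError):
        aggregate_formation([])


def test_aggregate_formation_permutation_invariant_and_bounded():
    from physchem.isodesmic import FormationEstimate

    values = [-300.8, -302.8, -299.2, -294.7, -295.9, -302.7]
    ests = [FormationEstimate(str(i), 0.0, v, 1.0) for i, v in enumerate(values)]
    mean1, ci1, _ = aggregate_formation(ests)
    mean2, ci2, _ = aggregate_formation(list(reversed(ests)))
    assert mean1 == pytest.approx(mean2, rel=1e-14)
    assert ci1 == pytest.approx(ci2, rel=1e-14)
    assert min(values) <= mean1 <= max(values)
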