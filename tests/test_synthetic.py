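"""Synthetic-ledger generators: determinism, inverse-construction soundness."""

import pytest

from physchem.cdft import global_indices
from physchem.ionization import cluster_from_records, log_p, pka_cluster_continuum
from physchem.isodesmic import (
    aggregate_formation,
    formation_enthalpy,
    reaction_enthalpy,
)
from physchem.ledger import assemble_enthalpy, record_for, write_ledger
from physchem.phase_transfer import fusion_enthalpy, phase_change_enthalpy
from physchem.redox import cycle_from_records, cycle_gibbs
from physchem.rrho import VibrationalSpectrum, thermo_state
from physchem.synthetic import FixtureSpec, make_random_ledger, make_rk_fixture


def test_rk_fixture_is_byte_identical(tmp_path):
    p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
    write_ledger(make_rk_fixture().records, p1)
    write_ledger(make_rk_fixture().records, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_random_ledger_reproducible_for_fixed_seed(tmp_path):
    p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
    write_ledger(make_random_ledger(FixtureSpec(seed=11))[0], p1)
    write_ledger(make_random_ledger(FixtureSpec(seed=11))[0], p2)
    assert p1.read_bytes() == p2.read_bytes()
    p3 = tmp_path / "c.yaml"
    write_ledger(make_random_ledger(FixtureSpec(seed=12))[0], p3)
    assert p1.read_bytes() != p3.read_bytes()


@pytest.mark.parametrize("seed", [0, 42, 123])
def test_zero_noise_pipeline_recovers_every_ground_truth(seed):
    """Inverse-construction soundness: generator∘pipeline = identity."""
    records, truth = make_random_ledger(FixtureSpec(seed=seed))

    lp = log_p(
        record_for(records, "X", "aqueous").gibbs_energy,
        record_for(records, "X", "octanol").gibbs_energy,
    )
    assert lp == pytest.approx(truth["log_p"], abs=1e-8)

    pk = pka_cluster_continuum(cluster_from_records(records, "X_2H2O", "X_anion_2H2O"))
    assert pk == pytest.approx(truth["pka"], abs=1e-8)

    dg = cycle_gibbs(
        cycle_from_records(records, {"X": 1}, {"X_radical": 1, "proton": 1})
    )
    assert dg == pytest.approx(truth["delta_g_aq_star"], abs=1e-7)

    enthalpies = {
        r.species_id: assemble_enthalpy(r)
        for r in records
        if r.phase == "gas" and r.electronic_energy is not None
    }
    estimates = [
        formation_enthalpy(s, reaction_enthalpy(s, enthalpies), truth["reference_table"])
        for s in truth["schemes"]
    ]
    mean, _, table = aggregate_formation(estimates)
    assert mean == pytest.approx(truth["delta_f_h"], abs=1e-6)
    assert table["delta_f_h"].std() == pytest.approx(0.0, abs=1e-6)

    vib = record_for(records, "X_vib", "gas")
    state = thermo_state(
        VibrationalSpectrum(tuple(vib.frequencies)),
        mass=vib.molar_mass,
        rotational_constants=vib.rotational_constants,
    )
    assert state.cv == pytest.approx(truth["cv"], abs=1e-8)

    x = record_for(records, "X", "gas")
    idx = global_indices(homo=x.homo_energy, lumo=x.lumo_energy)
    assert idx.gap == pytest.approx(truth["gap"], rel=1e-12)
    assert idx.mu == pytest.approx(truth["mu"], rel=1e-9, abs=1e-12)
    vertical = global_indices(
        ip=x.vertical_cation_energy - x.ground_energy,
        ea=x.ground_energy - x.vertical_anion_energy,
        route="vertical",
    )
    assert vertical.ip == pytest.approx(truth["ip"], rel=1e-12)
    assert vertical.ea == pytest.approx(truth["ea"], rel=1e-12)

    sd = record_for(records, "X_surface", "gas").surface_descriptors
    vap = phase_change_enthalpy(sd, "vaporization")
    sub = phase_change_enthalpy(sd, "sublimation")
    assert vap == pytest.approx(truth["delta_vap_h"], abs=1e-8)
    assert fusion_enthalpy(sub, vap) == pytest.approx(truth["delta_fus_h"], abs=1e-8)


def test_pinned_targets_are_honoured():
    targets = {"pka": 9.95, "log_p": 1.83, "delta_vap_h": 70.03, "delta_fus_h": 26.92}
    records, truth = make_random_ledger(FixtureSpec(seed=3, targets=targets))
    assert truth["pka"] == 9.95
    sd = record_for(records, "X_surface", "gas").surface_descriptors
    assert phase_change_enthalpy(sd, "vaporization") == pytest.approx(70.03, abs=1e-6)


@pytest.mark.parametrize("seed", [1, 2])
def test_noisy_cluster_pka_within_propagated_error(seed):
    """Gaussian noise of scale s on two cluster energies propagates to a pKa
    standard error of s·√2/(ln10·RT); recovery stays within 3σ."""
    noise = 0.1
    records, truth = make_random_ledger(FixtureSpec(seed=seed, noise=noise))
    pk = pka_cluster_continuum(cluster_from_records(records, "X_2H2O", "X_anion_2H2O"))
    # all four cluster species carry noise: RSS = s·√4 = 2s on the reaction
    sigma_full = noise * 2.0 / 5.708
    assert abs(pk - truth["pka"]) < 3 * sigma_full
    assert abs(pk - truth["pka"]) > 0  # noise actually applied


def test_sampled_ledgers_respect_physical_invariants():
    for seed in range(5):
        records, truth = make_random_ledger(FixtureSpec(seed=seed))
        vib = record_for(records, "X_vib", "gas")
        assert all(nu > 0 for nu in vib.frequencies)
        assert truth["ip"] > -truth["ea"]
        assert truth["delta_fus_h"] >= 0


def test_out_of_bounds_target_rejected():
    with pytest.raises(ValueError, match="bounds"):
        FixtureSpec(targets={"pka": 35.0})
    with pytest.raises(ValueError, match="unknown"):
        FixtureSpec(targets={"boiling_point": 400.0})
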