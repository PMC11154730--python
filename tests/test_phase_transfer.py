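"""Phase-change enthalpies and general-solubility-equation predictions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physchem.phase_transfer import (
    DEFAULT_PHASE_CHANGE_COEFFICIENTS,
    PhaseChangeCoefficients,
    SolubilityInput,
    SurfaceDescriptors,
    TransitionCoefficients,
    fusion_enthalpy,
    gse_solubility,
    molar_to_mass_conc,
    phase_change_enthalpy,
    walden_solubility,
)


def test_phase_change_functional_form():
    coeff = PhaseChangeCoefficients(
        vaporization=TransitionCoefficients(1.0, 1.0, 0.0),
        sublimation=TransitionCoefficients(0.0, 1.0, 5.0),
    )
    d = SurfaceDescriptors(surface_area=4.0, sigma_tot_sq=36.0, nu=0.25)
    assert phase_change_enthalpy(d, "vaporization", coeff) == pytest.approx(5.0)
    zero_sigma = SurfaceDescriptors(surface_area=4.0, sigma_tot_sq=0.0, nu=0.1)
    assert phase_change_enthalpy(zero_sigma, "sublimation", coeff) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        phase_change_enthalpy(d, "melting", coeff)


def test_rk_descriptors_reproduce_bundled_enthalpies(rk_fixture):
    from physchem.ledger import record_for

    d = record_for(rk_fixture.records, "RK", "gas").surface_descriptors
    vap = phase_change_enthalpy(d, "vaporization")
    sub = phase_change_enthalpy(d, "sublimation")
    assert vap == pytest.approx(70.03, abs=0.005)
    assert sub == pytest.approx(96.95, abs=0.005)
    assert fusion_enthalpy(sub, vap) == pytest.approx(26.92, abs=0.01)


def test_fusion_enthalpy_cases():
    assert fusion_enthalpy(96.95, 70.03) == pytest.approx(26.92, rel=1e-12)
    assert fusion_enthalpy(50.0, 50.0) == 0.0
    with pytest.raises(ValueError, match="unphysical"):
        fusion_enthalpy(100.0, 101.0)


def test_gse_at_melting_point_reduces_to_constant_minus_logp():
    log_s, _ = gse_solubility(
        SolubilityInput(delta_fus_h=30.0, melting_point=298.15, log_p=2.0)
    )
    assert log_s == pytest.approx(0.8 - 2.0, rel=1e-12)


@pytest.mark.parametrize(
    "dfus, expected",
    [(26.92, 0.0153), (22.75, 0.0202)],
)
def test_gse_solubility_reference_inputs(dfus, expected):
    # 298 K working temperature reproduces the reference numbers to 3 s.f.
    _, molar = gse_solubility(
        SolubilityInput(delta_fus_h=dfus, melting_point=357.58, log_p=1.83,
                        temperature=298.0)
    )
    assert molar == pytest.approx(expected, rel=0.01)


def test_walden_solubility_reference_inputs():
    log_s, molar = walden_solubility(357.58, 1.83)
    assert log_s == pytest.approx(0.5 - 0.01 * (84.43 - 25.0) - 1.83, rel=1e-12)
    assert molar == pytest.approx(0.012, rel=0.01)
    log_s25, molar25 = walden_solubility(298.15, 1.83)
    assert log_s25 == pytest.approx(0.5 - 1.83, rel=1e-12)
    _, s_neutral = walden_solubility(298.15, 0.0)
    assert s_neutral == pytest.approx(10**0.5, rel=1e-12)


@pytest.mark.parametrize(
    "molar, mass, expected",
    [(0.0153, 164.20, 2.51), (0.0, 100.0, 0.0), (1.0, 100.0, 100.0)],
)
def test_molar_to_mass_conc(molar, mass, expected):
    assert molar_to_mass_conc(molar, mass) == pytest.approx(expected, abs=0.005)


def test_molar_to_mass_conc_rejects_negative():
    with pytest.raises(ValueError):
        molar_to_mass_conc(-0.1, 100.0)


@given(
    st.floats(5.0, 50.0), st.floats(310.0, 450.0), st.floats(-2.0, 5.0),
    st.floats(0.5, 10.0),
)
@settings(max_examples=50, derandomize=True)
def test_gse_monotonic_in_each_input(dfus, tm, logp, ddfus):
    base, _ = gse_solubility(SolubilityInput(dfus, tm, logp))
    more_fusion, _ = gse_solubility(SolubilityInput(dfus + ddfus, tm, logp))
    higher_tm, _ = gse_solubility(SolubilityInput(dfus, tm + 10.0, logp))
    greasier, _ = gse_solubility(SolubilityInput(dfus, tm, logp + 0.5))
    assert more_fusion < base
    assert higher_tm < base
    assert greasier < base


def test_walden_monotonic():
    base, _ = walden_solubility(360.0, 1.0)
    assert walden_solubility(380.0, 1.0)[0] < base
    assert walden_solubility(360.0, 1.5)[0] < base


def test_walden_and_fusion_forms_agree_on_slope():
    """With the universal fusion entropy ΔfusH = 56.5·T_m (J/mol), the GSE
    melting-point slope matches Walden's 0.01/K to within ~1% — the forms
    are consistent approximations, not identities."""

    def gse_logs(tm):
        return gse_solubility(
            SolubilityInput(delta_fus_h=56.5 * tm / 1000.0, melting_point=tm,
                            log_p=1.0)
        )[0]

    tm = 360.0
    slope_gse = (gse_logs(tm + 1.0) - gse_logs(tm - 1.0)) / 2.0
    slope_walden = (
        walden_solubility(tm + 1.0, 1.0)[0] - walden_solubility(tm - 1.0, 1.0)[0]
    ) / 2.0
    assert slope_gse == pytest.approx(slope_walden, rel=0.02)
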