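"""Fusion enthalpy and aqueous solubility.

Surface descriptors → vaporization/sublimation enthalpies → fusion enthalpy
by Hess's law → general solubility equation (and the Walden melting-point-
only variant).
"""

from physchem import (
    SolubilityInput,
    fusion_enthalpy,
    gse_solubility,
    make_rk_fixture,
    molar_to_mass_conc,
    phase_change_enthalpy,
    walden_solubility,
)
from physchem.ionization import log_p
from physchem.ledger import record_for
from physchem.synthetic import RK_LITERATURE_FUSION_ENTHALPY, RK_MELTING_POINT_K

fixture = make_rk_fixture()
rec = record_for(fixture.records, "RK", "gas")
vap = phase_change_enthalpy(rec.surface_descriptors, "vaporization")
sub = phase_change_enthalpy(rec.surface_descriptors, "sublimation")
fus = fusion_enthalpy(sub, vap)
lp = log_p(
    record_for(fixture.records, "RK", "aqueous").gibbs_energy,
    record_for(fixture.records, "RK", "octanol").gibbs_energy,
)

print(f"ΔvapH = {vap:.2f}  ΔsubH = {sub:.2f}  →  ΔfusH = {fus:.2f} kJ/mol")
log_s, molar = gse_solubility(
    SolubilityInput(delta_fus_h=fus, melting_point=RK_MELTING_POINT_K, log_p=lp)
)
print(f"GSE (pipeline ΔfusH):   S = {molar:.4f} M "
      f"({molar_to_mass_conc(molar, fixture.molar_mass):.2f} mg/mL)")
_, lit = gse_solubility(
    SolubilityInput(delta_fus_h=RK_LITERATURE_FUSION_ENTHALPY,
                    melting_point=RK_MELTING_POINT_K, log_p=lp)
)
print(f"GSE (calorimetric 22.75): S = {lit:.4f} M")
_, wal = walden_solubility(RK_MELTING_POINT_K, lp)
print(f"Walden (melting point only): S = {wal:.4f} M")
print("A few hundredths molar: 'slightly soluble' — consistent across the")
print("three melting-behaviour treatments.")
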