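"""Electrode potentials from the solution thermochemical cycle.

Assembles ΔG*_aq for the one-electron, one-proton oxidation of the phenol
to its phenoxyl radical, converts to a potential vs SHE, and applies the
pH correction for the formal potential at pH 7.4.
"""

from physchem import cycle_from_records, make_rk_fixture, redox_state

records = make_rk_fixture().records
components = cycle_from_records(
    records, reactants={"RK": 1}, products={"RK_radical": 1, "proton": 1}
)
state = redox_state(components, n_protons=1, ph=7.4, couple_direction="oxidation")

print(f"ΔG*_aq  = {state.delta_g_aq_star:8.2f} kJ/mol")
print(f"E° (oxidation convention) = {state.e_vs_she:5.2f} V vs SHE")
print(f"ΔG′(pH 7.4) = {state.delta_g_aq_prime:8.1f} kJ/mol")
print(f"E′(pH 7.4)  = {state.e_formal:5.2f} V vs SHE")
print("The proton-coupled couple gains ln(10)RT ≈ 5.71 kJ/mol of driving")
print("force per pH unit; at pH 7.4 the formal potential is 1.29 V.")
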