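"""Conceptual-DFT global indices and a fragment-decomposed density of states."""

import numpy as np

from physchem import OrbitalSet, dos_curve, global_indices, make_rk_fixture
from physchem.ledger import record_for

rec = record_for(make_rk_fixture().records, "RK", "gas")
koopmans = global_indices(homo=rec.homo_energy, lumo=rec.lumo_energy)
vertical = global_indices(
    ip=rec.vertical_cation_energy - rec.ground_energy,
    ea=rec.ground_energy - rec.vertical_anion_energy,
    route="vertical",
)
print("route      mu      eta     omega   (eV)")
print(f"koopmans  {koopmans.mu:6.2f}  {koopmans.eta:6.2f}  {koopmans.omega:6.2f}")
print(f"vertical  {vertical.mu:6.2f}  {vertical.eta:6.2f}  {vertical.omega:6.2f}")
print("mu: tendency to exchange electron density; eta: resistance to it")
print("(full gap on the orbital route, half-difference on the vertical one);")
print("omega: electrophilicity.")

# Toy two-fragment DOS around the frontier orbitals
orbitals = OrbitalSet(
    energies=(-9.4, -8.1, rec.homo_energy, rec.lumo_energy),
    fragment_weights={"phenol": (0.3, 0.5, 0.8, 0.45),
                      "butanoyl": (0.7, 0.5, 0.2, 0.55)},
)
grid, tdos, pdos = dos_curve(orbitals, sigma=0.2)
i_homo = int(np.argmin(np.abs(grid - rec.homo_energy)))
print(f"\nat E_HOMO = {rec.homo_energy} eV: TDOS = {tdos[i_homo]:.2f}, "
      + ", ".join(f"{k} = {v[i_homo]:.2f}" for k, v in pdos.items()))
print("The fragment curves always sum to the total: the decomposition shows")
print("which part of the molecule carries each frontier state.")
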