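"""Cluster-continuum pKa, log P and the pH-dependent distribution coefficient."""

from physchem import log_d, log_p, make_rk_fixture, pka_cluster_continuum
from physchem.ionization import cluster_from_records
from physchem.ledger import record_for

records = make_rk_fixture().records
lp = log_p(
    record_for(records, "RK", "aqueous").gibbs_energy,
    record_for(records, "RK", "octanol").gibbs_energy,
)
pka = pka_cluster_continuum(cluster_from_records(records, "RK_2H2O", "RK_anion_2H2O"))

print(f"log P = {lp:.2f}   pKa = {pka:.2f}")
for ph in (1.0, 7.4, pka, 12.0):
    print(f"  pH {ph:5.2f}:  log D = {log_d(lp, pka, ph):6.2f}")
print("Below the pKa the neutral phenol dominates and log D ≈ log P; at")
print("pH = pKa it drops by log10(2) ≈ 0.30; far above it falls 1 per pH unit.")
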