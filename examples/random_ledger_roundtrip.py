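"""Round-trip check with a randomized synthetic ledger.

Samples ground-truth properties, back-computes a ledger from them, then runs
the pipeline forward and compares: at zero noise the recovery is exact.
"""

from physchem import FixtureSpec, make_random_ledger, pka_cluster_continuum
from physchem.ionization import cluster_from_records, log_p
from physchem.ledger import record_for

records, truth = make_random_ledger(FixtureSpec(seed=7))
pka = pka_cluster_continuum(cluster_from_records(records, "X_2H2O", "X_anion_2H2O"))
lp = log_p(
    record_for(records, "X", "aqueous").gibbs_energy,
    record_for(records, "X", "octanol").gibbs_energy,
)
print(f"pKa   truth {truth['pka']:8.4f}   recovered {pka:8.4f}")
print(f"log P truth {truth['log_p']:8.4f}   recovered {lp:8.4f}")

noisy, truth_n = make_random_ledger(FixtureSpec(seed=7, noise=0.5))
pka_n = pka_cluster_continuum(cluster_from_records(noisy, "X_2H2O", "X_anion_2H2O"))
print(f"with 0.5 kJ/mol noise on the cluster energies: pKa off by "
      f"{pka_n - truth_n['pka']:+.3f} pK units")
print("Every pipeline formula is affine in the energies, so the generator")
print("inverts each one exactly; noise propagates linearly (≈0.175 pK units")
print("per kJ/mol on each cluster energy).")
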