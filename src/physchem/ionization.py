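"""Partitioning and acid-base equilibria: log P, cluster-continuum pKa, log D.

log P follows from the transfer Gibbs energy between water and octanol,
log P = −ΔG_transfer / (ln 10 · R · T).  The pKa of a weak (monoprotic) acid
is computed without any proton solvation energy by way of a neutralization
against hydroxide with n explicit water molecules retained on both the acid
and its anion (the cluster-continuum scheme):

    HA·(H₂O)ₙ + OH⁻  ⇌  A⁻·(H₂O)ₙ + H₂O          (neutralization step)

whose equilibrium constant multiplied by the water autoprotolysis constant
over [H₂O] gives K_a; in log form

    pK_a = ΔG_neut / (ln 10 · R · T) + pK_a(water),

with pK_a(water) = 14 + log₁₀(55.33) ≈ 15.74 on the convention that treats
liquid water at its molar concentration.  The distribution coefficient for
an acid whose anion does not partition into octanol is

    log D = log P − log₁₀(1 + 10^(pH − pK_a)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import PKA_WATER, STANDARD_TEMPERATURE, ln10_rt_kjmol


@dataclass(frozen=True)
class AcidBaseCluster:
    """Gibbs energies (kJ·mol⁻¹, same solvation environment) of the four
    species in the hydroxide-neutralization equilibrium."""

    acid_cluster: float  # HA·(H₂O)ₙ
    anion_cluster: float  # A⁻·(H₂O)ₙ
    hydroxide: float  # OH⁻
    water: float  # H₂O
    n_explicit_waters: int = 2

    def reaction_gibbs(self) -> float:
        """ΔG of HA·(H₂O)ₙ + OH⁻ → A⁻·(H₂O)ₙ + H₂O, kJ·mol⁻¹."""
        return self.anion_cluster + self.water - self.acid_cluster - self.hydroxide


@dataclass(frozen=True)
class IonizationResult:
    pka: float
    log_p: float
    log_d: float
    ph: float
    n_explicit_waters: int = 2


def log_p(
    g_aqueous: float,
    g_octanol: float,
    temperature: float = STANDARD_TEMPERATURE,
) -> float:
    """Octanol-water partition coefficient from phase Gibbs energies.

    ΔG_transfer = G(octanol) − G(aqueous); a favorable (negative) transfer
    into octanol gives a positive log P.
    """
    return -(g_octanol - g_aqueous) / ln10_rt_kjmol(temperature)


def pka_cluster_continuum(
    cluster: AcidBaseCluster,
    temperature: float = STANDARD_TEMPERATURE,
    pka_water: float = PKA_WATER,
) -> float:
    """pK_a from the hydroxide-neutralization cluster reaction.

    ``pka_water`` defaults to 14 + log₁₀(55.33) ≈ 15.74; pass 14.0 to adopt
    the activity-of-water-equals-one convention instead.
    """
    return cluster.reaction_gibbs() / ln10_rt_kjmol(temperature) + pka_water


def cluster_from_records(
    records,
    acid_id: str,
    anion_id: str,
    hydroxide_id: str = "hydroxide",
    water_id: str = "water",
    phase: str = "aqueous",
    n_explicit_waters: int = 2,
) -> AcidBaseCluster:
    """Assemble the neutralization cluster from ledger Gibbs energies."""
    from .ledger import record_for

    def g(species: str) -> float:
        rec = record_for(records, species, phase)
        if rec.gibbs_energy is None:
            raise ValueError(f"species {species!r} has no Gibbs energy in {phase!r}")
        return rec.gibbs_energy

    return AcidBaseCluster(
        acid_cluster=g(acid_id),
        anion_cluster=g(anion_id),
        hydroxide=g(hydroxide_id),
        water=g(water_id),
        n_explicit_waters=n_explicit_waters,
    )


def log_d(log_p_value: float, pka: float, ph: float) -> float:
    """pH-dependent distribution coefficient of a monoprotic acid.

    Only the neutral form partitions into octanol, so log D ≤ log P, with
    equality in the low-pH limit and slope −1 per pH unit far above pK_a.
    """
    if not all(map(math.isfinite, (log_p_value, pka, ph))):
        raise ValueError("log_d requires finite log P, pKa and pH")
    return log_p_value - math.log10(1.0 + 10.0 ** (ph - pka))
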