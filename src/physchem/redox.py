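"""Electrode potentials from a solution-phase thermochemical cycle.

The aqueous reaction Gibbs energy ΔG*_aq of an oxidation (or reduction) is
assembled from the gas-phase reaction Gibbs energy and the solvation Gibbs
energies of every participant, plus an R·T·ln(24.46) standard-state
correction (1 bar gas → 1 M solution) for each species flagged as changing
standard state.  The Nernst relation converts it to an absolute potential,
E_abs = −ΔG/(n·F), referenced to the standard hydrogen electrode by
subtracting its absolute potential (4.44 V by default).

For a proton-coupled couple the standard value is adjusted to the formal
potential at a given pH through ΔG′ = ΔG*_aq − N·ln(10)·R·T·pH with N the
number of protons transferred, giving the textbook −59.16·N mV per pH unit
slope at 298.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    FARADAY_KJMOL_PER_VOLT,
    SHE_ABSOLUTE_V,
    STANDARD_TEMPERATURE,
    ln10_rt_kjmol,
    standard_state_correction,
)


@dataclass(frozen=True)
class CycleLeg:
    """One participant of the cycle: its solvation Gibbs energy (kJ·mol⁻¹),
    signed stoichiometry (+ products, − reactants) and whether the 1 bar →
    1 M standard-state correction applies to it."""

    species_id: str
    solvation_gibbs: float
    coefficient: int
    standard_state_flag: bool = True


@dataclass(frozen=True)
class CycleComponents:
    """Legs of the solution thermochemical cycle."""

    gas_reaction_gibbs: float  # kJ·mol⁻¹
    legs: tuple[CycleLeg, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RedoxState:
    delta_g_aq_star: float  # kJ·mol⁻¹
    delta_g_aq_prime: float  # kJ·mol⁻¹
    e_absolute: float  # V
    e_vs_she: float  # V
    e_formal: float  # V
    n_electrons: int
    n_protons: int
    ph: float
    temperature: float


def cycle_gibbs(
    components: CycleComponents, temperature: float = STANDARD_TEMPERATURE
) -> float:
    """ΔG*_aq of the cycle, kJ·mol⁻¹.

    Gas-phase reaction Gibbs energy plus signed solvation legs, plus one
    R·T·ln(24.46) per unit of signed stoichiometry on each flagged leg.
    """
    corr = standard_state_correction(temperature)
    total = components.gas_reaction_gibbs
    for leg in components.legs:
        total += leg.coefficient * leg.solvation_gibbs
        if leg.standard_state_flag:
            total += leg.coefficient * corr
    return total


def potential_vs_she(
    delta_g_aq_star: float,
    n_electrons: int = 1,
    couple_direction: str = "reduction",
    she_absolute: float = SHE_ABSOLUTE_V,
) -> float:
    """Electrode potential vs SHE from the aqueous reaction Gibbs energy.

    E_abs = −ΔG/(n·F) for the reduction direction, then E = E_abs − E(SHE).
    ``couple_direction="oxidation"`` negates the SHE-referenced value so the
    number applies to the couple written as an oxidation.
    """
    if n_electrons < 1:
        raise ValueError("n_electrons must be at least 1")
    e_abs = -delta_g_aq_star / (n_electrons * FARADAY_KJMOL_PER_VOLT)
    e_she = e_abs - she_absolute
    if couple_direction == "reduction":
        return e_she
    if couple_direction == "oxidation":
        return -e_she
    raise ValueError(f"couple_direction must be 'reduction' or 'oxidation', got {couple_direction!r}")


def formal_potential(
    delta_g_aq_star: float,
    n_protons: int,
    ph: float,
    temperature: float = STANDARD_TEMPERATURE,
    n_electrons: int = 1,
    she_absolute: float = SHE_ABSOLUTE_V,
) -> tuple[float, float]:
    """pH-corrected Gibbs energy and formal potential (ΔG′ in kJ·mol⁻¹, E′ in V).

    ΔG′ = ΔG*_aq − N·ln(10)·R·T·pH.  The potential is reported as
    |ΔG′|/(n·F) − E(SHE): the magnitude convention used for proton-coupled
    phenolic couples, positive for a strongly exergonic couple either way
    it is written.
    """
    if ph < 0:
        raise ValueError("ph must be non-negative")
    delta_g_prime = delta_g_aq_star - n_protons * ln10_rt_kjmol(temperature) * ph
    e_formal = abs(delta_g_prime) / (n_electrons * FARADAY_KJMOL_PER_VOLT) - she_absolute
    return delta_g_prime, e_formal


def couple_gibbs(e_formal_a: float, e_formal_b: float, n_electrons: int = 1) -> float:
    """ΔG (kJ·mol⁻¹) of electron transfer between two couples at equal
    conditions: ΔG = −n·F·(E_a − E_b)."""
    return -n_electrons * FARADAY_KJMOL_PER_VOLT * (e_formal_a - e_formal_b)


def cycle_from_records(
    records,
    reactants: dict[str, int],
    products: dict[str, int],
    gas_phase: str = "gas",
    solution_phase: str = "aqueous",
    standard_state_flags: dict[str, bool] | None = None,
) -> CycleComponents:
    """Build cycle components from ledger records carrying gas- and
    solution-phase Gibbs energies (solvation = G_solution − G_gas)."""
    from .ledger import record_for  # local import: ledger builds on this module's types

    flags = standard_state_flags or {}
    dg_gas = 0.0
    legs: list[CycleLeg] = []
    for side, sign in ((reactants, -1), (products, +1)):
        for species, nu in side.items():
            gas = record_for(records, species, gas_phase)
            sol = record_for(records, species, solution_phase)
            if gas.gibbs_energy is None or sol.gibbs_energy is None:
                raise ValueError(f"species {species!r}: missing Gibbs energy leg")
            dg_gas += sign * nu * gas.gibbs_energy
            legs.append(
                CycleLeg(
                    species_id=species,
                    solvation_gibbs=sol.gibbs_energy - gas.gibbs_energy,
                    coefficient=sign * nu,
                    standard_state_flag=flags.get(species, True),
                )
            )
    return CycleComponents(gas_reaction_gibbs=dg_gas, legs=tuple(legs))


def redox_state(
    components: CycleComponents,
    n_protons: int = 1,
    ph: float = 7.4,
    temperature: float = STANDARD_TEMPERATURE,
    n_electrons: int = 1,
    couple_direction: str = "oxidation",
) -> RedoxState:
    """Convenience assembly of the full redox report from cycle components."""
    dg_star = cycle_gibbs(components, temperature)
    e_abs = -dg_star / (n_electrons * FARADAY_KJMOL_PER_VOLT)
    e_she = potential_vs_she(dg_star, n_electrons, couple_direction)
    dg_prime, e_formal = formal_potential(
        dg_star, n_protons, ph, temperature, n_electrons
    )
    return RedoxState(
        delta_g_aq_star=dg_star,
        delta_g_aq_prime=dg_prime,
        e_absolute=e_abs,
        e_vs_she=e_she,
        e_formal=e_formal,
        n_electrons=n_electrons,
        n_protons=n_protons,
        ph=ph,
        temperature=temperature,
    )
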