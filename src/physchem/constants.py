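"""Physical constants and unit conversions used across the pipeline.

All conversion factors live here so that no module carries its own copy.
Energies are handled in three units: Hartree at the electronic-structure
boundary, kJ·mol⁻¹ for thermochemistry, and eV for orbital/ionic-state
quantities.  ``convert_energy`` is the single gateway between them.
"""

from __future__ import annotations

import math

# --- energy conversion -------------------------------------------------------
#: kJ·mol⁻¹ per Hartree (CODATA).
HARTREE_TO_KJMOL: float = 2625.4996
#: kJ·mol⁻¹ per eV (Faraday constant divided by 1000; see FARADAY below).
EV_TO_KJMOL: float = 96.485

# --- thermodynamic constants -------------------------------------------------
#: Molar gas constant, J·K⁻¹·mol⁻¹.
GAS_CONSTANT: float = 8.31446
#: Faraday constant expressed as kJ·mol⁻¹ per volt per electron.
FARADAY_KJMOL_PER_VOLT: float = 96.485
#: Absolute potential of the standard hydrogen electrode, V.
SHE_ABSOLUTE_V: float = 4.44
#: Molar concentration of liquid water, mol·L⁻¹.
WATER_MOLARITY: float = 55.33
#: Autoprotolysis constant of water at 298.15 K.
KW: float = 1e-14
#: Default working temperature, K.
STANDARD_TEMPERATURE: float = 298.15
#: Default standard-state pressure for gas-phase entropies, bar.
STANDARD_PRESSURE_BAR: float = 1.0

# --- fundamental constants (SI, CODATA 2018) for RRHO statistical mechanics --
PLANCK: float = 6.62607015e-34            # J·s
BOLTZMANN: float = 1.380649e-23           # J·K⁻¹
AVOGADRO: float = 6.02214076e23           # mol⁻¹
SPEED_OF_LIGHT_CM: float = 2.99792458e10  # cm·s⁻¹
AMU_KG: float = 1.66053906660e-27         # kg per atomic mass unit


def rt_kjmol(temperature: float) -> float:
    """R·T in kJ·mol⁻¹."""
    return GAS_CONSTANT * temperature / 1000.0


def ln10_rt_kjmol(temperature: float) -> float:
    """ln(10)·R·T in kJ·mol⁻¹ — the per-log-unit Gibbs energy."""
    return math.log(10.0) * rt_kjmol(temperature)


def standard_state_correction(temperature: float = STANDARD_TEMPERATURE) -> float:
    """Gibbs-energy correction R·T·ln(24.46) in kJ·mol⁻¹.

    Moves a gas-phase species from the 1 bar ideal-gas standard state to the
    1 M solution standard state (24.46 L·mol⁻¹ is the molar volume of an
    ideal gas at 298.15 K and 1 atm).
    """
    return rt_kjmol(temperature) * math.log(24.46)


#: pKa of water on the 55.33 M convention: 14 + log10([H2O]).
PKA_WATER: float = -math.log10(KW) + math.log10(WATER_MOLARITY)


_TO_KJMOL = {
    "hartree": HARTREE_TO_KJMOL,
    "kj/mol": 1.0,
    "ev": EV_TO_KJMOL,
    "kcal/mol": 4.184,
}

_ALIASES = {
    "hartree": "hartree",
    "eh": "hartree",
    "au": "hartree",
    "kj/mol": "kj/mol",
    "kj·mol-1": "kj/mol",
    "kjmol": "kj/mol",
    "ev": "ev",
    "kcal/mol": "kcal/mol",
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a molar energy between Hartree, kJ·mol⁻¹, eV and kcal·mol⁻¹.

    Pure linear scaling through kJ·mol⁻¹; raises ``ValueError`` for a unit
    outside the supported set (the dimensionally-incompatible case).
    """
    try:
        src = _ALIASES[from_unit.strip().lower()]
        dst = _ALIASES[to_unit.strip().lower()]
    except KeyError as exc:
        raise ValueError(f"unsupported or incompatible energy unit: {exc}") from exc
    return value * _TO_KJMOL[src] / _TO_KJMOL[dst]
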