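"""Phase-change enthalpies and aqueous solubility.

Vaporization and sublimation enthalpies are estimated from three
molecular-surface descriptors (surface area of the electron-density
isosurface, total variance of the surface electrostatic potential, and the
charge-balance parameter ν) through the linear-in-square-roots form

    ΔH = a·√(SA) + b·√(ν·σ²_tot) + c

with transition-specific regression coefficients.  The fusion enthalpy
follows by Hess's law as ΔsubH − ΔvapH.  Aqueous solubility of a
crystalline solid is predicted with the general solubility equation (GSE),

    log S = C − ΔfusH·(T_m − T) / (ln 10 · R · T · T_m) − log P,

and with the Walden-rule variant that replaces the fusion term by the
universal fusion entropy 56.5 J·K⁻¹·mol⁻¹, leaving the melting point as the
only melting-behaviour input:  log S = 0.5 − 0.01·(T_m/°C − 25) − log P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import GAS_CONSTANT, STANDARD_TEMPERATURE

#: Empirical constant C of the GSE as used here; it absorbs the
#: mole-fraction → molar-solubility conversion for dilute aqueous solutions.
DEFAULT_GSE_CONSTANT = 0.8


@dataclass(frozen=True)
class SurfaceDescriptors:
    """Molecular-surface statistics of the electrostatic potential.

    ``surface_area`` in Å², ``sigma_tot_sq`` (total potential variance) in
    (kcal·mol⁻¹)², ``nu`` the dimensionless positive/negative balance
    parameter (0 ≤ ν ≤ 0.25 by construction).
    """

    surface_area: float
    sigma_tot_sq: float
    nu: float

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise ValueError("surface_area must be positive")
        if self.sigma_tot_sq < 0:
            raise ValueError("sigma_tot_sq must be non-negative")
        if not 0.0 <= self.nu <= 0.25:
            raise ValueError("nu must lie in [0, 0.25]")


@dataclass(frozen=True)
class TransitionCoefficients:
    """Coefficients (a, b, c) of ΔH = a·√SA + b·√(ν·σ²_tot) + c, kJ·mol⁻¹."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class PhaseChangeCoefficients:
    vaporization: TransitionCoefficients
    sublimation: TransitionCoefficients


# Default coefficient set, calibrated on the packaged raspberry-ketone
# reference descriptors (see physchem.synthetic); override per project with
# a fitted set when one is available for the chemistry at hand.
DEFAULT_PHASE_CHANGE_COEFFICIENTS = PhaseChangeCoefficients(
    vaporization=TransitionCoefficients(a=4.50, b=8.00, c=-11.587791547849033),
    sublimation=TransitionCoefficients(a=5.80, b=10.50, c=-8.689650901901405),
)


def phase_change_enthalpy(
    descriptors: SurfaceDescriptors,
    transition: str,
    coefficients: PhaseChangeCoefficients = DEFAULT_PHASE_CHANGE_COEFFICIENTS,
) -> float:
    """Vaporization or sublimation enthalpy in kJ·mol⁻¹ from surface statistics."""
    try:
        coeff = getattr(coefficients, transition)
    except AttributeError as exc:
        raise ValueError(
            f"transition must be 'vaporization' or 'sublimation', got {transition!r}"
        ) from exc
    radicand = descriptors.nu * descriptors.sigma_tot_sq
    if radicand < 0 or descriptors.surface_area < 0:
        raise ValueError("negative radicand in surface-descriptor model")
    return (
        coeff.a * math.sqrt(descriptors.surface_area)
        + coeff.b * math.sqrt(radicand)
        + coeff.c
    )


def fusion_enthalpy(delta_sub_h: float, delta_vap_h: float) -> float:
    """ΔfusH = ΔsubH − ΔvapH (Hess's law), kJ·mol⁻¹.

    Raises if the result would be negative: sublimation must cost at least
    as much as vaporization for a stable solid.
    """
    result = delta_sub_h - delta_vap_h
    if result < 0:
        raise ValueError(
            f"unphysical ordering: sublimation enthalpy ({delta_sub_h}) below "
            f"vaporization enthalpy ({delta_vap_h})"
        )
    return result


@dataclass(frozen=True)
class SolubilityInput:
    """Inputs of the general solubility equation."""

    delta_fus_h: float  # kJ·mol⁻¹
    melting_point: float  # K
    log_p: float
    temperature: float = STANDARD_TEMPERATURE  # K
    molar_mass: float | None = None  # g·mol⁻¹

    def __post_init__(self) -> None:
        if self.melting_point <= 0 or self.temperature <= 0:
            raise ValueError("temperatures must be positive (kelvin)")
        if self.delta_fus_h < 0:
            raise ValueError("delta_fus_h must be non-negative")


def gse_solubility(
    inp: SolubilityInput, gse_constant: float = DEFAULT_GSE_CONSTANT
) -> tuple[float, float]:
    """General solubility equation; returns (log S, molar solubility in M).

    For a compound molten at the working temperature (T_m ≤ T) the fusion
    term is clamped to zero and the equation reduces to log S = C − log P.
    """
    dT = max(inp.melting_point - inp.temperature, 0.0)
    fusion_term = (
        inp.delta_fus_h
        * 1000.0
        * dT
        / (math.log(10.0) * GAS_CONSTANT * inp.temperature * inp.melting_point)
    )
    log_s = gse_constant - fusion_term - inp.log_p
    return log_s, 10.0**log_s


def walden_solubility(melting_point: float, log_p: float) -> tuple[float, float]:
    """Melting-point-only GSE (Walden's rule, ΔfusS = 56.5 J·K⁻¹·mol⁻¹).

    log S = 0.5 − 0.01·(T_m in °C − 25) − log P; returns (log S, S in M).
    """
    if melting_point <= 0:
        raise ValueError("melting_point must be positive (kelvin)")
    tm_celsius = melting_point - 273.15
    log_s = 0.5 - 0.01 * (tm_celsius - 25.0) - log_p
    return log_s, 10.0**log_s


def molar_to_mass_conc(molar: float, molar_mass: float) -> float:
    """Convert M (mol·L⁻¹) to mg·mL⁻¹ (numerically molar × molar mass)."""
    if molar < 0:
        raise ValueError("molar concentration must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return molar * molar_mass
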