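"""Ideal-gas thermodynamic functions under the rigid-rotor harmonic-oscillator model.

Translation is treated by Sackur–Tetrode, rotation by the classical rigid
rotor (with symmetry number), and each vibrational mode by the quantum
harmonic oscillator with the zero-point energy reported separately from the
thermal correction.  The enthalpy correction includes the PV term
(H = U + RT) and Cp = Cv + R holds exactly, as it must for an ideal gas.

No quasi-RRHO or free-rotor damping of low-frequency modes is applied: the
model is the conventional RRHO.  Frequencies enter unscaled by default; a
global scaling factor is exposed because harmonic wavenumbers from hybrid
functionals are often scaled in composite schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .constants import (
    AMU_KG,
    AVOGADRO,
    BOLTZMANN,
    GAS_CONSTANT,
    PLANCK,
    SPEED_OF_LIGHT_CM,
    STANDARD_PRESSURE_BAR,
    STANDARD_TEMPERATURE,
)

_R = GAS_CONSTANT  # J·K⁻¹·mol⁻¹


@dataclass(frozen=True)
class VibrationalSpectrum:
    """Harmonic wavenumbers (cm⁻¹) with optional degeneracies (default 1)."""

    wavenumbers: tuple[float, ...]
    degeneracies: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.degeneracies is not None and len(self.degeneracies) != len(
            self.wavenumbers
        ):
            raise ValueError("degeneracies must match wavenumbers in length")
        if self.degeneracies is not None and any(g < 1 for g in self.degeneracies):
            raise ValueError("degeneracies must be positive integers")

    def modes(self) -> list[tuple[float, int]]:
        gs = self.degeneracies or (1,) * len(self.wavenumbers)
        return list(zip(self.wavenumbers, gs))


@dataclass
class ThermoComponents:
    """One motion's contribution: internal thermal energy U (kJ·mol⁻¹),
    entropy S and heat capacity Cv (J·K⁻¹·mol⁻¹)."""

    internal_energy: float = 0.0
    entropy: float = 0.0
    cv: float = 0.0


@dataclass
class ThermoState:
    """Ideal-gas thermodynamic functions of one species at (T, p)."""

    temperature: float
    pressure: float
    zpve: float  # kJ·mol⁻¹
    h_corr: float  # kJ·mol⁻¹, thermal enthalpy correction incl. RT
    entropy: float  # J·K⁻¹·mol⁻¹
    cv: float  # J·K⁻¹·mol⁻¹
    cp: float  # J·K⁻¹·mol⁻¹
    components: dict[str, ThermoComponents] = field(default_factory=dict)


def zpve(spectrum: VibrationalSpectrum, scale: float = 1.0) -> float:
    """Zero-point vibrational energy ½·N_A·h·c·Σ gᵢν̃ᵢ in kJ·mol⁻¹."""
    total = 0.0
    for nu, g in spectrum.modes():
        if nu < 0:
            raise ValueError(f"imaginary mode (negative wavenumber {nu}); not a minimum")
        total += g * nu
    joules_per_mol = 0.5 * AVOGADRO * PLANCK * SPEED_OF_LIGHT_CM * scale * total
    return joules_per_mol / 1000.0


def _translational(mass: float, temperature: float, pressure: float) -> ThermoComponents:
    m = mass * AMU_KG  # molecular mass in kg; g·mol⁻¹ numerically equals amu
    p = pressure * 1e5  # bar → Pa
    q = (2.0 * math.pi * m * BOLTZMANN * temperature / PLANCK**2) ** 1.5 * (
        BOLTZMANN * temperature / p
    )
    return ThermoComponents(
        internal_energy=1.5 * _R * temperature / 1000.0,
        entropy=_R * (math.log(q) + 2.5),
        cv=1.5 * _R,
    )


def _rotational(
    rotational_constants: Sequence[float],
    linear: bool,
    symmetry_number: int,
    temperature: float,
) -> ThermoComponents:
    if not rotational_constants:
        return ThermoComponents()
    # Rotational temperatures Θ = hB/k with B in Hz (input GHz).
    thetas = [PLANCK * b * 1e9 / BOLTZMANN for b in rotational_constants]
    if linear:
        if len(set(rotational_constants)) > 1:
            raise ValueError("a linear rotor has a single rotational constant")
        q = temperature / (symmetry_number * thetas[0])
        return ThermoComponents(
            internal_energy=_R * temperature / 1000.0,
            entropy=_R * (math.log(q) + 1.0),
            cv=_R,
        )
    if len(thetas) != 3:
        raise ValueError("a nonlinear rotor needs three rotational constants")
    q = (math.sqrt(math.pi) / symmetry_number) * math.sqrt(
        temperature**3 / (thetas[0] * thetas[1] * thetas[2])
    )
    return ThermoComponents(
        internal_energy=1.5 * _R * temperature / 1000.0,
        entropy=_R * (math.log(q) + 1.5),
        cv=1.5 * _R,
    )


def _vibrational(
    spectrum: VibrationalSpectrum, temperature: float, scale: float
) -> ThermoComponents:
    comp = ThermoComponents()
    for nu, g in spectrum.modes():
        if nu < 0:
            raise ValueError(f"imaginary mode (negative wavenumber {nu}); not a minimum")
        if nu == 0:
            continue
        theta = PLANCK * SPEED_OF_LIGHT_CM * scale * nu / BOLTZMANN
        x = theta / temperature
        # e^{-x} formulation stays finite for arbitrarily stiff modes
        em = math.exp(-x)
        occ = em / (1.0 - em)  # 1/(e^x - 1)
        comp.internal_energy += g * _R * theta * occ / 1000.0
        comp.entropy += g * _R * (x * occ - math.log1p(-em))
        comp.cv += g * _R * x**2 * em / (1.0 - em) ** 2
    return comp


def thermo_state(
    spectrum: VibrationalSpectrum,
    mass: float,
    rotational_constants: Sequence[float] = (),
    linear: bool = False,
    temperature: float = STANDARD_TEMPERATURE,
    pressure: float = STANDARD_PRESSURE_BAR,
    symmetry_number: int = 1,
    frequency_scale: float = 1.0,
) -> ThermoState:
    """Full RRHO thermodynamic state of an ideal-gas species.

    ``mass`` in g·mol⁻¹, ``rotational_constants`` in GHz (empty for an
    atom), ``pressure`` in bar.  The thermal enthalpy correction includes
    RT; the ZPVE is reported separately.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    if symmetry_number < 1:
        raise ValueError("symmetry_number must be a positive integer")

    trans = _translational(mass, temperature, pressure)
    rot = _rotational(rotational_constants, linear, symmetry_number, temperature)
    vib = _vibrational(spectrum, temperature, frequency_scale)

    cv = trans.cv + rot.cv + vib.cv
    entropy = trans.entropy + rot.entropy + vib.entropy
    u_thermal = trans.internal_energy + rot.internal_energy + vib.internal_energy
    h_corr = u_thermal + _R * temperature / 1000.0  # H = U + RT
    return ThermoState(
        temperature=temperature,
        pressure=pressure,
        zpve=zpve(spectrum, scale=frequency_scale),
        h_corr=h_corr,
        entropy=entropy,
        cv=cv,
        cp=cv + _R,
        components={"translational": trans, "rotational": rot, "vibrational": vib},
    )
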