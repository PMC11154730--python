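"""Conceptual-DFT global reactivity descriptors and density-of-states curves.

Two routes to the global indices are supported.  The Koopmans route reads
the vertical ionization energy and electron affinity off the frontier
orbitals (I = −E_HOMO, A = −E_LUMO); the vertical (ΔSCF) route takes I and
A from explicit ionic-state energies.  The electronic chemical potential is
μ = −(I + A)/2 in both.  For hardness two conventions circulate: the full
HOMO-LUMO gap, η = I − A, and the conventional half-difference,
η = (I − A)/2.  Results carry both, explicitly labelled, because published
index tables mix them; the electrophilicity index ω = μ²/(2η) is evaluated
with the half-gap hardness on the Koopmans route (equivalently μ²/gap) and
with the reported half-difference hardness on the vertical route, which is
how mixed-convention tables are in fact constructed.

The density of states broadens each orbital energy with a unit-area
Gaussian; fragment weights partition the total curve into per-fragment
partial curves that sum back to the total pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CDFTIndices:
    """Global reactivity indices, all in eV."""

    mu: float  # electronic chemical potential
    eta_gap: float  # hardness, full-gap convention (I − A)
    eta_half: float  # hardness, half-difference convention (I − A)/2
    omega: float  # electrophilicity index (see module docstring)
    gap: float  # I − A; equals E_LUMO − E_HOMO on the Koopmans route
    ip: float
    ea: float
    route: str  # "koopmans" | "vertical"
    environment: str = "gas"

    @property
    def eta(self) -> float:
        """Reported hardness: full gap on the Koopmans route, half-difference
        on the vertical route (the convention each route's tables use)."""
        return self.eta_gap if self.route == "koopmans" else self.eta_half


def global_indices(
    homo: float | None = None,
    lumo: float | None = None,
    ip: float | None = None,
    ea: float | None = None,
    route: str = "koopmans",
    environment: str = "gas",
) -> CDFTIndices:
    """Global CDFT indices from (homo, lumo) or from vertical (ip, ea), eV.

    Koopmans route: I = −E_HOMO, A = −E_LUMO (requires homo < lumo).
    Vertical route: I and A given directly (requires I > A, i.e. a positive
    chemical hardness).
    """
    if route == "koopmans":
        if homo is None or lumo is None:
            raise ValueError("koopmans route needs homo and lumo energies")
        if homo >= lumo:
            raise ValueError("homo energy must lie strictly below lumo energy")
        i_val, a_val = -homo, -lumo
        gap = lumo - homo
        mu = -(i_val + a_val) / 2.0
        omega = mu**2 / gap  # = μ²/(2·η_half)
    elif route == "vertical":
        if ip is None or ea is None:
            raise ValueError("vertical route needs ip and ea")
        if ip <= ea:
            raise ValueError("vertical ip must exceed ea")
        i_val, a_val = ip, ea
        gap = i_val - a_val
        mu = -(i_val + a_val) / 2.0
        omega = mu**2 / (2.0 * (gap / 2.0))  # μ²/(2·η_half), η_half = (I−A)/2
    else:
        raise ValueError(f"route must be 'koopmans' or 'vertical', got {route!r}")
    return CDFTIndices(
        mu=mu,
        eta_gap=gap,
        eta_half=gap / 2.0,
        omega=omega,
        gap=gap,
        ip=i_val,
        ea=a_val,
        route=route,
        environment=environment,
    )


@dataclass(frozen=True)
class OrbitalSet:
    """Orbital energies (eV, ascending) with per-orbital fragment weights.

    ``fragment_weights`` maps fragment name → array of per-orbital weights;
    across fragments the weights of each orbital must sum to 1.
    """

    energies: tuple[float, ...]
    fragment_weights: dict[str, tuple[float, ...]] | None = None
    occupations: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if list(self.energies) != sorted(self.energies):
            raise ValueError("orbital energies must be ascending")
        if self.fragment_weights:
            w = np.array(list(self.fragment_weights.values()))
            if w.shape[1] != len(self.energies):
                raise ValueError("fragment weights must match orbital count")
            if not np.allclose(w.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("fragment weights of each orbital must sum to 1")


def dos_curve(
    orbitals: OrbitalSet,
    sigma: float = 0.2,
    grid: np.ndarray | None = None,
    grid_step: float = 0.01,
    padding: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Gaussian-broadened total and per-fragment density of states.

    Returns ``(grid, tdos, pdos)`` with unit-area Gaussians of width
    ``sigma`` (eV) on each orbital, so the TDOS integrates to the number of
    orbitals and the PDOS curves sum to the TDOS at every grid point.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    energies = np.asarray(orbitals.energies, dtype=float)
    if grid is None:
        lo = energies.min() - padding * sigma if energies.size else -1.0
        hi = energies.max() + padding * sigma if energies.size else 1.0
        grid = np.arange(lo, hi + grid_step, grid_step)
    # shape (n_orbitals, n_grid) of unit-area Gaussians
    kernels = np.exp(-((grid[None, :] - energies[:, None]) ** 2) / (2 * sigma**2)) / (
        sigma * np.sqrt(2 * np.pi)
    )
    tdos = kernels.sum(axis=0)
    pdos: dict[str, np.ndarray] = {}
    if orbitals.fragment_weights:
        for name, weights in orbitals.fragment_weights.items():
            pdos[name] = (np.asarray(weights, dtype=float)[:, None] * kernels).sum(axis=0)
    return grid, tdos, pdos
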