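"""End-to-end property report assembled from a species ledger.

Chains the individual modules into the full inference: isodesmic formation
enthalpy with uncertainty, partitioning (log P, pKa, log D), fusion
enthalpy and aqueous solubility, electrode potentials, and the
conceptual-DFT indices for every environment present on the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cdft import CDFTIndices, global_indices
from .constants import STANDARD_TEMPERATURE
from .ionization import cluster_from_records, log_d, log_p, pka_cluster_continuum
from .isodesmic import (
    aggregate_formation,
    formation_enthalpy,
    load_reference_table,
    reaction_enthalpy,
)
from .ledger import QCRecord, assemble_enthalpy, record_for, records_for
from .phase_transfer import (
    DEFAULT_GSE_CONSTANT,
    SolubilityInput,
    fusion_enthalpy,
    gse_solubility,
    molar_to_mass_conc,
    phase_change_enthalpy,
)
from .redox import RedoxState, cycle_from_records, redox_state
from .synthetic import RKFixture


@dataclass
class PropertyReport:
    """Assembled physicochemical property set for one molecule."""

    species_id: str
    temperature: float
    formation_mean: float | None = None
    formation_ci95: float | None = None
    formation_table: pd.DataFrame | None = None
    log_p: float | None = None
    pka: float | None = None
    ph: float | None = None
    log_d: float | None = None
    delta_vap_h: float | None = None
    delta_sub_h: float | None = None
    delta_fus_h: float | None = None
    log_s: float | None = None
    molar_solubility: float | None = None
    mass_solubility: float | None = None
    redox: RedoxState | None = None
    cdft: dict[str, dict[str, CDFTIndices]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flat two-column (property, value) view for tabular output."""
        rows: list[tuple[str, float]] = []
        for name in (
            "formation_mean",
            "formation_ci95",
            "log_p",
            "pka",
            "log_d",
            "delta_vap_h",
            "delta_sub_h",
            "delta_fus_h",
            "log_s",
            "molar_solubility",
            "mass_solubility",
        ):
            value = getattr(self, name)
            if value is not None:
                rows.append((name, value))
        if self.redox is not None:
            rows += [
                ("delta_g_aq_star", self.redox.delta_g_aq_star),
                ("delta_g_aq_prime", self.redox.delta_g_aq_prime),
                ("e_vs_she", self.redox.e_vs_she),
                ("e_formal", self.redox.e_formal),
            ]
        for env, routes in self.cdft.items():
            for route, idx in routes.items():
                rows += [
                    (f"cdft_{env}_{route}_mu", idx.mu),
                    (f"cdft_{env}_{route}_eta", idx.eta),
                    (f"cdft_{env}_{route}_omega", idx.omega),
                ]
        return pd.DataFrame(rows, columns=["property", "value"])


def analyze_rk(
    fixture: RKFixture,
    ph: float = 7.4,
    temperature: float = STANDARD_TEMPERATURE,
    gse_constant: float = DEFAULT_GSE_CONSTANT,
) -> PropertyReport:
    """Run the complete pipeline on the raspberry-ketone fixture ledger."""
    records = fixture.records
    report = PropertyReport(species_id="RK", temperature=temperature, ph=ph)

    # Formation enthalpy from the six isodesmic schemes.
    references = load_reference_table()
    enthalpies = {
        rec.species_id: assemble_enthalpy(rec)
        for rec in records
        if rec.phase == "gas" and rec.electronic_energy is not None
    }
    estimates = [
        formation_enthalpy(s, reaction_enthalpy(s, enthalpies), references)
        for s in fixture.schemes
    ]
    report.formation_mean, report.formation_ci95, report.formation_table = (
        aggregate_formation(estimates)
    )

    # Partitioning and ionization.
    rk_aq = record_for(records, "RK", "aqueous")
    rk_oct = record_for(records, "RK", "octanol")
    report.log_p = log_p(rk_aq.gibbs_energy, rk_oct.gibbs_energy, temperature)
    cluster = cluster_from_records(records, "RK_2H2O", "RK_anion_2H2O")
    report.pka = pka_cluster_continuum(cluster, temperature)
    report.log_d = log_d(report.log_p, report.pka, ph)

    # Phase change and solubility.
    rk_gas = record_for(records, "RK", "gas")
    descriptors = rk_gas.surface_descriptors
    report.delta_vap_h = phase_change_enthalpy(
        descriptors, "vaporization", fixture.coefficients
    )
    report.delta_sub_h = phase_change_enthalpy(
        descriptors, "sublimation", fixture.coefficients
    )
    report.delta_fus_h = fusion_enthalpy(report.delta_sub_h, report.delta_vap_h)
    report.log_s, report.molar_solubility = gse_solubility(
        SolubilityInput(
            delta_fus_h=report.delta_fus_h,
            melting_point=fixture.melting_point,
            log_p=report.log_p,
            temperature=temperature,
            molar_mass=fixture.molar_mass,
        ),
        gse_constant=gse_constant,
    )
    report.mass_solubility = molar_to_mass_conc(
        report.molar_solubility, fixture.molar_mass
    )

    # Redox: one-electron, one-proton oxidation to the phenoxyl radical.
    components = cycle_from_records(
        records, reactants={"RK": 1}, products={"RK_radical": 1, "proton": 1}
    )
    report.redox = redox_state(
        components, n_protons=1, ph=ph, temperature=temperature, n_electrons=1
    )

    # CDFT indices per environment, both routes.
    for phase in ("gas", "aqueous", "lipid"):
        recs = records_for(records, "RK", phase)
        rec = recs[0] if recs else None
        if rec is None or rec.homo_energy is None:
            continue
        env: dict[str, CDFTIndices] = {}
        env["koopmans"] = global_indices(
            homo=rec.homo_energy, lumo=rec.lumo_energy, environment=phase
        )
        if rec.vertical_cation_energy is not None:
            ip = rec.vertical_cation_energy - rec.ground_energy
            ea = rec.ground_energy - rec.vertical_anion_energy
            env["vertical"] = global_indices(
                ip=ip, ea=ea, route="vertical", environment=phase
            )
        report.cdft[phase] = env
    return report
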