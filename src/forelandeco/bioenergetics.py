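"""Thermodynamic power-per-cell model for atmospheric trace-gas oxidation.

For each gas (H2, CO, CH4) the aerobic oxidation reaction is described by
its stoichiometry and standard Gibbs energy; the Gibbs energy under soil
conditions follows from the reaction quotient over gas-phase activities
(partial pressure / 1 atm; liquid water at activity 1):

    dG = dG0 + R T ln Q

Power per cell combines the bulk oxidation rate (mol per g dry soil per
second), |dG| (J mol^-1) and the number of oxidiser cells per g dry soil
(total 16S rRNA gene copies x the fraction of cells carrying the relevant
oxidation gene), and is compared against the empirical maintenance-power
window of 1e-17 to 1e-12 W per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import (MAINTENANCE_POWER_MAX_W, MAINTENANCE_POWER_MIN_W,
                        R_J_PER_MOL_K)

#: Standard Gibbs energies of formation at 298.15 K, kJ mol^-1
#: (CODATA/standard thermodynamic tables; gases at 1 atm, water liquid).
GIBBS_FORMATION_KJ = {
    "H2": 0.0,
    "O2": 0.0,
    "H2O(l)": -237.14,
    "CO": -137.17,
    "CO2": -394.39,
    "CH4": -50.5,
}


@dataclass(frozen=True)
class GasSpecies:
    """One trace gas and its aerobic oxidation reaction.

    ``stoichiometry`` maps species to signed coefficients (reactants
    negative). ``default_activities`` hold soil-air defaults for
    co-reactants and products; the trace gas's own activity comes from its
    atmospheric mixing ratio unless overridden.
    """

    name: str
    stoichiometry: dict
    delta_g0_kj: float
    atm_mixing_ratio_ppmv: float
    default_activities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_g0_kj >= 0:
            raise ValueError(
                f"{self.name}: oxidation must be exergonic at standard state")


def _delta_g0_from_formation(stoich: dict) -> float:
    return sum(nu * GIBBS_FORMATION_KJ[sp] for sp, nu in stoich.items())


def default_species() -> dict[str, GasSpecies]:
    """Registry for the three atmospheric trace gases, with standard
    Gibbs energies derived from formation energies and soil-air default
    activities (O2 0.209 atm, CO2 420 ppmv, liquid water activity 1)."""
    common = {"O2": 0.209, "CO2": 420e-6, "H2O(l)": 1.0}
    specs = {}
    for name, stoich, c_atm in [
        ("H2", {"H2": -1.0, "O2": -0.5, "H2O(l)": 1.0}, 0.5),
        ("CO", {"CO": -1.0, "O2": -0.5, "CO2": 1.0}, 0.6),
        ("CH4", {"CH4": -1.0, "O2": -2.0, "CO2": 1.0, "H2O(l)": 2.0}, 1.8),
    ]:
        specs[name] = GasSpecies(
            name=name, stoichiometry=stoich,
            delta_g0_kj=_delta_g0_from_formation(stoich),
            atm_mixing_ratio_ppmv=c_atm,
            default_activities={sp: common[sp] for sp in stoich
                                if sp in common})
    return specs


def load_species_yaml(path: str | Path) -> dict[str, GasSpecies]:
    """Load a species registry from YAML (name, stoichiometry, delta_g0_kj,
    atm_mixing_ratio_ppmv, default_activities)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: GasSpecies(name=name, **entry) for name, entry in raw.items()}


def gibbs_energy(species: GasSpecies,
                 activities: dict | None = None,
                 temperature_k: float = 298.15) -> float:
    """Gibbs energy of the oxidation under given conditions, kJ mol^-1.

    ``activities`` are dimensionless (partial pressure / 1 atm for gases);
    missing species fall back to the registry defaults, and the trace gas
    itself defaults to its atmospheric mixing ratio. The standard Gibbs
    energy is used as-is (no enthalpy correction), which is flagged only
    through the explicit temperature argument.
    """
    acts = dict(species.default_activities)
    acts.setdefault(species.name, species.atm_mixing_ratio_ppmv * 1e-6)
    if activities:
        acts.update(activities)
    ln_q = 0.0
    for sp, nu in species.stoichiometry.items():
        a = acts.get(sp, 1.0)
        if a <= 0:
            raise ValueError(f"non-positive activity for {sp}")
        ln_q += nu * math.log(a)
    return species.delta_g0_kj + R_J_PER_MOL_K * temperature_k * ln_q / 1000.0


@dataclass
class PowerResult:
    gas: str
    site: str
    rate_mol_per_gdw_s: float
    delta_g_kj: float
    n_oxidizer_cells_per_gdw: float
    power_w_per_cell: float
    within_maintenance_window: bool


def power_per_cell(gas: str, site: str,
                   rate_nmol_per_gdw_h: float,
                   delta_g_kj: float,
                   cells_per_gdw: float,
                   oxidizer_fraction: float) -> PowerResult:
    """Power per putative oxidiser cell, W.

    ``oxidizer_fraction`` is the fraction of cells carrying the gene
    (average gene copy per organism capped at 1 by the caller); combined
    with total cell counts per g dry soil it gives the oxidiser count.
    """
    if cells_per_gdw <= 0:
        raise ValueError("cell count must be positive")
    if not 0 < oxidizer_fraction <= 1:
        if oxidizer_fraction == 0 and rate_nmol_per_gdw_h > 0:
            raise ValueError("nonzero rate with zero oxidiser fraction is "
                             "inconsistent")
        raise ValueError("oxidizer_fraction must be in (0, 1]")
    rate_mol_s = rate_nmol_per_gdw_h * 1e-9 / 3600.0
    n_ox = cells_per_gdw * oxidizer_fraction
    power = rate_mol_s * abs(delta_g_kj) * 1000.0 / n_ox
    return PowerResult(
        gas=gas, site=site, rate_mol_per_gdw_s=rate_mol_s,
        delta_g_kj=delta_g_kj, n_oxidizer_cells_per_gdw=n_ox,
        power_w_per_cell=power,
        within_maintenance_window=(
            MAINTENANCE_POWER_MIN_W <= power <= MAINTENANCE_POWER_MAX_W))


def summarize_power(results: list[PowerResult]) -> dict:
    """Mean, min and max power per cell over gas-site combinations, and
    the fraction inside the maintenance window."""
    if not results:
        raise ValueError("no power results to summarise")
    powers = np.array([r.power_w_per_cell for r in results])
    return {
        "n": len(results),
        "mean_w_per_cell": float(powers.mean()),
        "min_w_per_cell": float(powers.min()),
        "max_w_per_cell": float(powers.max()),
        "fraction_in_maintenance_window": float(
            np.mean([r.within_maintenance_window for r in results])),
    }
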