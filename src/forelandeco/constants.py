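"""Physical constants and unit conversions used across the rate and
thermodynamic calculations.

Everything dimensional passes through this registry so that unit
conventions (atm, ppmv, nmol) are defined exactly once.
"""

#: Universal gas constant, J mol^-1 K^-1.
R_J_PER_MOL_K = 8.31446

#: Standard atmosphere, Pa.
ATM_PA = 101325.0

#: Gas constant in L atm mol^-1 K^-1 (derived; used for headspace moles).
R_L_ATM_PER_MOL_K = R_J_PER_MOL_K / ATM_PA * 1000.0

#: Mean Earth radius (WGS84 sphere), km — great-circle distances.
EARTH_RADIUS_KM = 6371.0088

#: Empirical microbial maintenance-power window, W cell^-1.
MAINTENANCE_POWER_MAX_W = 1e-12
MAINTENANCE_POWER_MIN_W = 1e-17

PPMV = 1e-6  # mole fraction per ppmv


def moles_in_headspace(mixing_ratio_ppmv: float, volume_l: float,
                       temperature_k: float = 298.15,
                       pressure_atm: float = 1.0) -> float:
    """Moles of a trace gas in a headspace, from the ideal gas law.

    Parameters are the gas mixing ratio (ppmv), headspace volume (L),
    temperature (K) and total pressure (atm). Returns mol.
    """
    total_mol = pressure_atm * volume_l / (R_L_ATM_PER_MOL_K * temperature_k)
    return mixing_ratio_ppmv * PPMV * total_mol


def molar_density_air(temperature_k: float = 298.15,
                      pressure_atm: float = 1.0) -> float:
    """Molar density of air (mol m^-3) at the given T and P."""
    return pressure_atm * ATM_PA / (R_J_PER_MOL_K * temperature_k)
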