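"""Unit constants and conversions.

Internally the model works in SI (m, s) with MCPA concentrations in micromolar
units of carbon: dissolved C_L [umol C / m^3 water], sorbed C_S [umol C / kg
soil], degrader biomass B [umol C / kg soil].  The reporting layer converts to
mass-based concentrations (mg/kg, ug/kg, ug/L) and field-scale rates (kg/ha)
using the molar mass of MCPA and its number of carbon atoms.
"""

from __future__ import annotations

#: MCPA molar mass [g/mol]
MCPA_MOLAR_MASS = 200.62
#: carbon atoms per MCPA molecule [1]
MCPA_N_CARBON = 9
#: water density [kg/m^3]
RHO_WATER = 1.0e3
#: gravitational acceleration [m/s^2]
GRAVITY = 9.81

SECONDS_PER_DAY = 86400.0

#: micrograms of MCPA per umol of MCPA-carbon
_UG_MCPA_PER_UMOL_C = MCPA_MOLAR_MASS / MCPA_N_CARBON


def mm_per_day_to_m_per_s(rate: float) -> float:
    """Convert an infiltration rate from mm/d to m/s."""
    return rate * 1.0e-3 / SECONDS_PER_DAY


def m_per_s_to_mm_per_day(rate: float) -> float:
    return rate * 1.0e3 * SECONDS_PER_DAY


def days_to_seconds(t):
    return t * SECONDS_PER_DAY


def seconds_to_days(t):
    return t / SECONDS_PER_DAY


def umolC_per_kg_to_mg_per_kg(c):
    """umol C / kg soil -> mg MCPA / kg soil."""
    return c * _UG_MCPA_PER_UMOL_C * 1.0e-3


def umolC_per_kg_to_ug_per_kg(c):
    """umol C / kg soil -> ug MCPA / kg soil."""
    return c * _UG_MCPA_PER_UMOL_C


def umolC_per_m3_to_ug_per_L(c):
    """umol C / m^3 water -> ug MCPA / L water."""
    return c * _UG_MCPA_PER_UMOL_C * 1.0e-3


def kg_per_ha_to_umolC_per_m2(rate_kg_ha: float) -> float:
    """Areal application rate kg MCPA / ha -> umol C / m^2."""
    g_per_m2 = rate_kg_ha * 1000.0 / 1.0e4
    mol_mcpa = g_per_m2 / MCPA_MOLAR_MASS
    return mol_mcpa * MCPA_N_CARBON * 1.0e6
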