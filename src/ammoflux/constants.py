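"""Physical constants and fixed model parameters.

All constants used anywhere in the package live here, so that a single
versioned registry documents the numerical assumptions of the analysis.
Concentrations are carried internally in mmol/L, which is numerically
identical to mol/m^3; this makes the flux equation
``q = P * a_m * (c_out - c_in)`` dimensionally clean with P in m/h and
a_m in m^2/g_CDW (the product is mol/g/h, i.e. 1e-3 mmol/g/h).
"""

from __future__ import annotations

#: Universal gas constant, J/(mol K)
R_GAS_J_PER_MOL_K = 8.314462618

#: Faraday constant, C/mol
FARADAY_C_PER_MOL = 96485.33212

#: Acid dissociation exponent of the ammonium/ammonia couple.  The
#: room-temperature literature value; every tabulated quantity in the
#: reference dataset is consistent with this value used uncorrected at
#: 30 degC, so no temperature correction is applied by default.
DEFAULT_PKA = 9.25

#: Cultivation temperature, kelvin (30 degC).
DEFAULT_TEMPERATURE_K = 303.15

#: Molar mass of glucose, g/mol, used for biomass yield on substrate.
GLUCOSE_MOLAR_MASS_G_PER_MOL = 180.16

#: Biomass-specific membrane area, m^2/g_CDW.
DEFAULT_MEMBRANE_AREA_M2_PER_G = 3.22

#: Biomass nitrogen content used in the batch growth law, mol N/g_CDW.
DEFAULT_BIOMASS_N_MOL_PER_G = 5.60e-3

#: Plasma-membrane proton motive force, mV, negative inside.  Not a
#: measured quantity in the reference dataset; chosen because it
#: reproduces the tabulated uniport equilibrium-ratio bounds (see
#: docs/methods.md).
DEFAULT_PMF_MV = -200.0

#: ATP stoichiometry of respiration under respirofermentative,
#: N-limited conditions, mol ATP/mol O2.
DEFAULT_ATP_PER_O2 = 1.9

#: ATP stoichiometry of alcoholic fermentation, mol ATP/mol ethanol.
DEFAULT_ATP_PER_ETHANOL = 1.0

CONSTANTS_VERSION = "1.0"


def registry() -> dict[str, float | str]:
    """Return the versioned constants registry as a plain dict."""
    return {
        "version": CONSTANTS_VERSION,
        "R_gas_J_per_mol_K": R_GAS_J_PER_MOL_K,
        "faraday_C_per_mol": FARADAY_C_PER_MOL,
        "pKa_ammonium": DEFAULT_PKA,
        "temperature_K": DEFAULT_TEMPERATURE_K,
        "glucose_molar_mass_g_per_mol": GLUCOSE_MOLAR_MASS_G_PER_MOL,
        "membrane_area_m2_per_g": DEFAULT_MEMBRANE_AREA_M2_PER_G,
        "biomass_N_mol_per_g": DEFAULT_BIOMASS_N_MOL_PER_G,
        "pmf_mV": DEFAULT_PMF_MV,
        "atp_per_O2": DEFAULT_ATP_PER_O2,
        "atp_per_ethanol": DEFAULT_ATP_PER_ETHANOL,
    }
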