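"""Physical constants and shipped default parameter sets.

Kinetic constants for the carboxylation model follow the widely used
temperature-response compilation of Bernacchi and co-workers; all values are
overridable through :class:`cassleaf.fvcb.PhotoParams`.
"""

from __future__ import annotations

# Universal gas constant, kJ mol-1 K-1
R_GAS = 8.314e-3

# Reference temperature for parameter normalisation
T_REF_C = 25.0
T_REF_K = 298.15

# Michaelis constant of Rubisco for CO2 at 25 C (umol mol-1) and its
# activation energy (kJ mol-1)
KC25 = 404.9
KC_HA = 79.43

# Michaelis constant of Rubisco for O2 at 25 C (mmol mol-1)
KO25 = 278.4
KO_HA = 36.38

# Photorespiratory CO2 compensation point at 25 C (umol mol-1)
GAMMA_STAR25 = 42.75
GAMMA_STAR_HA = 37.83

# Day respiration activation energy (kJ mol-1)
RD_HA = 46.39

# Activation energies for the capacity parameters (kJ mol-1).  The
# triose-phosphate ceiling is kept temperature-flat by default: a ceiling
# rising faster than electron transport would never bind at warm leaf
# temperatures, contrary to the observed high-CO2 flattening.
VCMAX_HA = 65.33
JMAX_HA = 43.54
TPU_HA = 0.0

# Peaked-function deactivation defaults for Vcmax/Jmax normalisation
HD_DEFAULT = 200.0     # kJ mol-1
DS_DEFAULT = 0.65      # kJ mol-1 K-1

# Oxygen mole fraction, mmol mol-1
O2_DEFAULT = 210.0

# Light response of electron transport (incident basis)
ALPHA_DEFAULT = 0.425
THETA_DEFAULT = 0.9

# Fluorescence-to-electron-transport defaults
ABSORPTANCE_DEFAULT = 0.85
BETA_DEFAULT = 0.5

# Ratio of water-vapour to CO2 diffusivity through stomata
GSW_TO_GSC = 1.6

# Default cuvette environment
CA_DEFAULT = 400.0       # umol mol-1
TLEAF_DEFAULT = 28.0     # C
VPD_DEFAULT = 1.5        # kPa
PATM_DEFAULT = 101.325   # kPa


def saturation_vapour_pressure(t_c: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature ``t_c`` (C).

    Tetens formulation; adequate for cuvette humidity bookkeeping.
    """
    import math

    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def relative_humidity_from_vpd(vpd_kpa: float, t_c: float) -> float:
    """Fractional relative humidity implied by a VPD at leaf temperature."""
    es = saturation_vapour_pressure(t_c)
    rh = 1.0 - vpd_kpa / es
    return min(max(rh, 0.0), 1.0)
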