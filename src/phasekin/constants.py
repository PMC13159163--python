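"""Physical constants and shared named quantities (strict SI internally)."""

from scipy.constants import Avogadro as N_A
from scipy.constants import Boltzmann as KB
from scipy.constants import gas_constant as R_GAS
from scipy.constants import zero_Celsius as T_ZERO_C

__all__ = [
    "N_A",
    "KB",
    "R_GAS",
    "T_ZERO_C",
    "RAPID_NUCLEATION_RATE",
    "MW_POLY_RA",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Rate (m^-3 s^-1) above which nucleation is considered biologically rapid;
#: also the experimental lower bound inferred from the microdroplet assay.
RAPID_NUCLEATION_RATE = 1.0e12

#: Single effective molecular weight used for poly-rA RNA (kg mol^-1);
#: polydispersity of the sample is ignored throughout.
MW_POLY_RA = 2500.0


def celsius_to_kelvin(t_c):
    """Convert degrees Celsius to kelvin (I/O boundary helper)."""
    return t_c + T_ZERO_C


def kelvin_to_celsius(t_k):
    """Convert kelvin to degrees Celsius (I/O boundary helper)."""
    return t_k - T_ZERO_C
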