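"""Physical constants (CODATA 2018, frozen via scipy.constants).

All electrostatic formulas in the package read from this single table so
that thermal voltages, Debye lengths, etc. are always evaluated from
constants rather than from rounded shortcuts such as "25.7 mV".
"""

from scipy import constants as _c

#: elementary charge, C
E_CHARGE: float = _c.e
#: Boltzmann constant, J/K
K_BOLTZMANN: float = _c.k
#: Avogadro constant, 1/mol
N_AVOGADRO: float = _c.N_A
#: vacuum permittivity, F/m
EPS0: float = _c.epsilon_0
#: Faraday constant, C/mol
FARADAY: float = _c.physical_constants["Faraday constant"][0]
#: molar gas constant, J/(mol K)
R_GAS: float = _c.R


def thermal_voltage(temperature: float) -> float:
    """kB*T/e in volts (~25.7 mV at 298.15 K)."""
    return K_BOLTZMANN * temperature / E_CHARGE


def ph_shift_per_volt(temperature: float) -> float:
    """F/(RT ln 10): pH units per volt of local potential (~16.9 /V at 25 C).

    This is the coefficient written as 0.434*F/RT in potential-modified
    Henderson-Hasselbalch expressions; 0.434 is log10(e), evaluated exactly.
    """
    import math

    return FARADAY / (R_GAS * temperature * math.log(10.0))
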