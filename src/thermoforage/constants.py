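"""Physical constants and unit helpers shared across modules.

All Arrhenius-type arithmetic is done in Kelvin with energies in
electron-volts, the convention of the metabolic theory of ecology.
Tabular interfaces (CSV, config files) carry temperatures in degrees
Celsius; conversion happens exactly once, at module boundaries.
"""

from __future__ import annotations

#: Boltzmann's constant in eV per Kelvin.
BOLTZMANN_EV: float = 8.617e-5

#: Offset between the Celsius and Kelvin scales.
KELVIN_OFFSET: float = 273.15

#: Micromoles per mole.
UMOL_PER_MOL: float = 1e6

#: Kilograms per milligram.
KG_PER_MG: float = 1e-6


def celsius_to_kelvin(temp_c):
    """Convert a temperature (scalar or array) from °C to K."""
    return temp_c + KELVIN_OFFSET


def kelvin_to_celsius(temp_k):
    """Convert a temperature (scalar or array) from K to °C."""
    return temp_k - KELVIN_OFFSET
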