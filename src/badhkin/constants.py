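"""Shared physical constants and unit helpers.

Interfaces throughout the package accept temperatures in degrees Celsius
(matching how enzyme assays are reported); thermodynamic and Arrhenius
arithmetic is done in kelvin internally.
"""

GAS_CONSTANT = 8.314
"""Molar gas constant R, J mol^-1 K^-1."""

CELSIUS_OFFSET = 273.15

STANDARD_TEMPERATURE_K = 298.15
"""Default temperature for equilibrium arithmetic (25 degC)."""


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
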