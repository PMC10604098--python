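"""Physical constants and unit conversions used throughout the package.

Internal convention: file formats and user-facing APIs use nm, °C, MHz/kHz;
physics formulas (Stokes-Einstein, moduli, force spectra) run in SI.
"""

BOLTZMANN = 1.380649e-23  # J/K

NM_TO_M = 1e-9
M_TO_NM = 1e9
NM2_TO_UM2 = 1e-6
UM2_TO_NM2 = 1e6
NM2_TO_M2 = 1e-18
UM2_TO_M2 = 1e-12
MHZ_TO_KHZ = 1e3
KHZ_TO_MHZ = 1e-3

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET
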