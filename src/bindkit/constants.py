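"""Physical constants and unit helpers.

All internal equations use kelvin, molar, litres and kcal; interfaces that
accept Celsius convert immediately on entry.
"""

#: Gas constant in kcal mol^-1 K^-1 (used for dG = RT ln Kd and van't Hoff factors).
R_KCAL: float = 1.98720e-3

#: Conversion: 1 kcal = 1e9 microcalories.
KCAL_TO_UCAL: float = 1.0e9

#: Default tryptophan fluorescence lifetime (s).
TRP_LIFETIME_S: float = 1.0e-8

#: van der Waals radii (angstrom) used by the surface-area calculation.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

#: Water probe radius (angstrom).
WATER_PROBE_RADIUS: float = 1.4


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15
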