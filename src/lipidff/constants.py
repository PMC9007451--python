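"""Physical constants shared by the analysis modules."""

# Bound coherent neutron scattering lengths, fm (Sears, Neutron News 3, 1992).
# "D" is deuterium; water hydrogens are interpolated H<->D by the D2O fraction.
COHERENT_SCATTERING_LENGTHS_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
    "S": 2.847,
    "Na": 3.63,
    "K": 3.67,
    "Cl": 9.5770,
    "Ca": 4.70,
    "Mg": 5.375,
}

# Electron density of TIP3P-like water near ambient conditions, e/A^3.
WATER_ELECTRON_DENSITY = 0.333

# Number density of water near ambient conditions, molecules/A^3 (~30 A^3 each).
WATER_NUMBER_DENSITY = 1.0 / 30.0

ELEMENT_Z: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12,
    "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20,
}
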