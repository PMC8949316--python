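"""Monoisotopic element and ion masses (CODATA/IUPAC), single source of truth.

All masses in Da, 6+ decimal places. Charged-adduct shifts fold the electron
mass into the proton/cation mass so that theoretical m/z is obtained by a
single addition to the neutral monoisotopic mass.
"""

MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825,
    "O": 15.994915,
    "N": 14.003074,
    "P": 30.973762,
    "S": 31.972071,
}

ELECTRON_MASS = 0.000549

# m/z shift of the ion relative to the neutral molecule M
PROTON_MASS = 1.007276                   # [M+H]+ / [M-H]-
SODIUM_CATION_MASS = 22.989218           # 22Na - e-
POTASSIUM_CATION_MASS = 38.963158        # 39K - e-

# instrument scan ranges used for simulated chemical-noise peaks (Da)
SCAN_RANGE = {"negative": (550.0, 1000.0), "positive": (480.0, 1000.0)}
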