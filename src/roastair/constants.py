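"""Physical and regulatory constants used across the package.

Exposure limits are configuration values, not hard-coded logic: every
function that compares against a limit takes it as an argument and merely
defaults to the constants here.
"""

#: Molar masses (g/mol) of the alpha-dicarbonyl analytes, from their
#: molecular formulas (C4H6O2 and C5H8O2).
MOLAR_MASS_G_MOL: dict[str, float] = {
    "diacetyl": 86.09,
    "2,3-pentanedione": 100.12,
}

#: Molar volume of an ideal gas at 25 degC and 1 atm (L/mol); the convention
#: used for mg/m3 <-> ppb conversion.
MOLAR_VOLUME_L_MOL: float = 24.45

#: NIOSH recommended exposure limit for diacetyl, full-shift TWA (ppb).
DIACETYL_REL_PPB: float = 5.0

#: NIOSH short-term (15-min) exposure limit for diacetyl (ppb).
DIACETYL_STEL_PPB: float = 25.0

#: Literature total diacetyl content of roasted coffee (ug chemical per g
#: coffee); used for the emitted-mass sanity bound.
DIACETYL_CONTENT_UG_G: float = 19.0

#: Standard 8-h shift length in minutes.
SHIFT_LENGTH_MIN: float = 480.0
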