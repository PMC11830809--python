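"""Physical constants shared across modules (SI units)."""

FARADAY = 96_485.0
"""Faraday constant, C per mol of electrons."""

GAS_CONSTANT = 8.314
"""Molar gas constant, J/(mol K)."""

GRAMS_O2_PER_MOL_E = 8.0
"""COD equivalence: 4 electrons per 32 g O2, i.e. 8 g O2 per mol of electrons."""

H2_ELECTRONS = 2
"""Electrons per mole of H2 (2H+ + 2e- -> H2)."""

SECONDS_PER_DAY = 86_400.0

DEFAULT_CATHOLYTE_VOLUME_L = 0.25
DEFAULT_DURATION_S = 6 * SECONDS_PER_DAY
DEFAULT_CATHODE_AREA_CM2 = 1.5 * 1.5
DEFAULT_CATHODE_POTENTIAL_V_SHE = -0.6
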