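"""Physical constants and unit conventions.

All internal lengths are in nm, forces in pN, energies in kcal/mol,
denaturant concentrations in M.  Contour-length increments are converted
to Å only at the presentation layer.
"""

# Thermal energy at 298 K (25 degC), pN nm.
KBT_PN_NM = 4.114

# Gas constant times temperature at 298 K, kcal/mol.
RT_KCAL_MOL = 0.592

# Boltzmann constant in pN nm / K (scaled from the 298 K anchor).
KB_PN_NM_PER_K = KBT_PN_NM / 298.0

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


def kbt(temperature_k: float = 298.0) -> float:
    """Thermal energy in pN nm at the given temperature."""
    return KB_PN_NM_PER_K * temperature_k
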