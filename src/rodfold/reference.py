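"""Published reference values for the SasG G5/E repeat region.

These numbers parameterize the synthetic-data generators (they define the
conditions the recovery experiments emulate) and serve as the comparison
column in the ``rodfold reproduce`` report.

Conventions
-----------
Equilibrium parameters are *unfolding* quantities: positive dG means the
construct is stable.  Per-domain stabilities in DOMAIN_FOLDING_DG use the
*folding* convention (negative = stable); the E domain is intrinsically
disordered in isolation, so its folding free energy carries a lower bound
(at least +2.5 kcal/mol, i.e. at least that unstable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KBT_PN_NM


@dataclass(frozen=True)
class EquilibriumRow:
    """Two-state urea denaturation parameters for one construct."""

    m: float        # kcal mol^-1 M^-1
    m_se: float
    d50: float      # M urea
    d50_se: float
    dg: float       # kcal/mol (unfolding)
    dg_se: float


#: Apparent equilibrium parameters per construct (urea denaturation, 25 degC).
EQUILIBRIUM: dict[str, EquilibriumRow] = {
    "G5_1":            EquilibriumRow(1.0, 0.1, 3.2, 0.1, 3.2, 0.1),
    "G5_1-E":          EquilibriumRow(1.0, 0.1, 3.2, 0.1, 3.2, 0.1),
    "G5_2":            EquilibriumRow(1.0, 0.1, 2.8, 0.1, 2.8, 0.1),
    "E-G5_2":          EquilibriumRow(1.4, 0.1, 4.4, 0.1, 6.3, 0.2),
    "E-G5_2-FRET-A":   EquilibriumRow(1.4, 0.1, 4.3, 0.1, 6.1, 0.3),
    "E-G5_2-FRET-B":   EquilibriumRow(1.4, 0.1, 4.3, 0.1, 6.1, 0.4),
    "G5_1-E-G5_2":     EquilibriumRow(1.5, 0.1, 4.9, 0.1, 7.5, 0.2),
}


@dataclass(frozen=True)
class AfmRow:
    """Pooled modal AFM statistics at one retraction speed."""

    speed: float          # nm/s
    n_e: int
    n_g5: int
    force_e: float        # pN, mode
    force_e_sd: float
    force_g5: float
    force_g5_sd: float
    dlc_e_a: float        # Angstrom, mode
    dlc_e_sd: float
    dlc_g5_a: float
    dlc_g5_sd: float


#: Modal unfolding force and contour-length increment per retraction speed.
AFM_SPEED_TABLE: dict[int, AfmRow] = {
    200:  AfmRow(200, 126, 52, 212, 25, 351, 34, 149, 15, 219, 9),
    800:  AfmRow(800, 409, 146, 250, 35, 421, 36, 145, 12, 216, 6),
    1500: AfmRow(1500, 597, 229, 229, 27, 379, 28, 154, 10, 224, 8),
    3000: AfmRow(3000, 258, 149, 254, 35, 397, 53, 152, 12, 224, 13),
    5000: AfmRow(5000, 547, 263, 265, 37, 408, 35, 153, 13, 227, 9),
}

#: Canonical retraction-speed grid, nm/s.
CANONICAL_SPEEDS = (200, 800, 1500, 3000, 5000)

#: Individual domain folding free energies, kcal/mol (folding convention,
#: negative = stable).  bound: 'exact' or 'ge' (true value >= quoted).
DOMAIN_FOLDING_DG = {
    "G5_1": (-3.2, "exact"),
    "E": (+2.5, "ge"),
    "G5_2": (-2.8, "exact"),
}

#: SHRImP end-to-end distance for the 13-domain construct: mean +/- s.e., nm.
SHRIMP_MEAN_NM = 59.0
SHRIMP_SE_NM = 5.0

#: Rigid crystal-structure-based model length of the 13-domain construct, nm.
MODEL_LENGTH_13_NM = 71.0
#: Crystal length of the three-domain fragment, nm.
MODEL_LENGTH_3_NM = 17.0

#: Construct composition of the mechanical (13-domain) polyprotein.
N_G5 = 7
N_E = 6


def bell_xu_from_speed_series(class_name: str) -> float:
    """Distance to the unfolding transition state (nm) for 'E' or 'G5'.

    Bell-Evans: the modal unfolding force grows linearly with ln(speed)
    with slope kBT/xu, so xu follows from a least-squares line through the
    published mode-force-vs-speed series.
    """
    rows = [AFM_SPEED_TABLE[v] for v in CANONICAL_SPEEDS]
    lnv = np.log([r.speed for r in rows])
    if class_name == "E":
        f = np.array([r.force_e for r in rows])
    elif class_name == "G5":
        f = np.array([r.force_g5 for r in rows])
    else:
        raise ValueError(f"unknown domain class {class_name!r}")
    slope = np.polyfit(lnv, f, 1)[0]
    return KBT_PN_NM / slope
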