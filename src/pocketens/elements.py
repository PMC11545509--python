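"""Element property tables used throughout the geometry code.

Van der Waals radii (Å, Bondi-style values) and Pauling electronegativities
for the elements that occur in protein/heme systems.  The apolar rule used
for pocket hydrophobicity counts contacting atoms whose Pauling
electronegativity is below :data:`APOLAR_EN_CUTOFF`; both tables can be
overridden per call where relevant.
"""

from __future__ import annotations

# Bondi vdW radii in Å; FE uses a covalent-ish value common in cavity tools.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "SE": 1.90,
}

# Pauling electronegativities.
PAULING_EN: dict[str, float] = {
    "H": 2.20,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "S": 2.58,
    "P": 2.19,
    "F": 3.98,
    "CL": 3.16,
    "BR": 2.96,
    "I": 2.66,
    "FE": 1.83,
    "ZN": 1.65,
    "MG": 1.31,
    "NA": 0.93,
    "K": 0.82,
    "CA": 1.00,
    "SE": 2.55,
}

#: Pauling-electronegativity threshold below which an atom counts as apolar.
APOLAR_EN_CUTOFF: float = 2.8

DEFAULT_VDW = 1.70  # fall back to carbon for exotic elements
DEFAULT_EN = 2.55


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def electronegativity(element: str) -> float:
    """Pauling electronegativity for an element symbol (case-insensitive)."""
    return PAULING_EN.get(element.upper(), DEFAULT_EN)


def is_apolar(element: str, cutoff: float = APOLAR_EN_CUTOFF) -> bool:
    """True if the element's electronegativity is below the apolar cutoff."""
    return electronegativity(element) < cutoff
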