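"""Element data tables used across parsing, featurization and charge assignment.

Radii are in Angstrom.  Covalent radii follow the Cordero consensus values;
Van der Waals radii follow Bondi (with common extensions for metals).
"""

from __future__ import annotations

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "As": 1.19, "Se": 1.20,
    "Br": 1.20, "I": 1.39,
    "Li": 1.28, "Na": 1.66, "Mg": 1.41, "K": 2.03, "Ca": 1.76,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Cd": 1.44, "Hg": 1.32, "Sr": 1.95, "Cs": 2.44, "Ba": 2.15,
}

VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "As": 1.85, "Se": 1.90,
    "Br": 1.85, "I": 1.98,
    "Li": 1.82, "Na": 2.27, "Mg": 1.73, "K": 2.75, "Ca": 2.31,
    "Mn": 2.05, "Fe": 2.05, "Co": 2.00, "Ni": 1.63, "Cu": 1.40, "Zn": 1.39,
    "Cd": 1.58, "Hg": 1.55, "Sr": 2.49, "Cs": 3.43, "Ba": 2.68,
}
VDW_FALLBACK = 1.70

HALOGENS = frozenset({"F", "Cl", "Br", "I", "At"})
METALS = frozenset({
    "Li", "Na", "Mg", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Cd", "Hg", "Sr", "Cs", "Ba",
})

KNOWN_ELEMENTS = frozenset(COVALENT_RADII)

# One-hot element classes, in slot order.
ELEMENT_CLASSES = ("B", "C", "N", "O", "P", "S", "Se", "halogen", "metal")

# PEOE (Gasteiger-Marsili) electronegativity parameters (a, b, c) keyed by
# (element, hybridization code); hybridization 0 falls back to the sp3 row.
PEOE_PARAMS: dict[tuple[str, int], tuple[float, float, float]] = {
    ("H", 0): (7.17, 6.24, -0.56),
    ("C", 3): (7.98, 9.18, 1.88),
    ("C", 2): (8.79, 9.32, 1.51),
    ("C", 1): (10.39, 9.45, 0.73),
    ("N", 3): (11.54, 10.82, 1.36),
    ("N", 2): (12.87, 11.15, 0.85),
    ("N", 1): (15.68, 11.70, -0.27),
    ("O", 3): (14.18, 12.92, 1.39),
    ("O", 2): (17.07, 13.79, 0.47),
    ("F", 3): (14.66, 13.85, 2.31),
    ("Cl", 3): (11.00, 9.69, 1.35),
    ("Br", 3): (10.08, 8.47, 1.16),
    ("I", 3): (9.90, 7.96, 0.96),
    ("S", 3): (10.14, 9.13, 1.38),
    ("P", 3): (8.90, 8.24, 0.96),
}
PEOE_FALLBACK = (8.0, 9.0, 1.5)
PEOE_H_CATION = 20.02

# Typical neutral valences used by the donor heuristic.
TYPICAL_VALENCE = {"N": 3, "O": 2, "S": 2, "C": 4}


def normalize_element(symbol: str) -> str:
    """'CL' -> 'Cl', 'c' -> 'C'."""
    s = symbol.strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()
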