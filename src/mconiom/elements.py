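"""Element data: atomic masses and single-bond covalent radii.

The covalent radii drive two things: the link-atom scale factor
k_ab = (R_a + R_H) / (R_a + R_b) used to place hydrogen caps on cut
bonds, and the default bond-inference rule (bonded iff the distance is
below 1.15 x the radii sum).  The shipped values are the Pyykkoe-Atsumi
single-bond radii for Z <= 36; both tables can be overridden by passing
an explicit mapping to the functions that consume them.
"""

from __future__ import annotations

__all__ = [
    "ATOMIC_MASSES",
    "COVALENT_RADII",
    "atomic_mass",
    "covalent_radius",
    "normalize_symbol",
]

# Standard atomic weights (amu), CIAAW conventional values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798,
}

# Single-bond covalent radii (Angstroem), Pyykkoe & Atsumi, Z <= 36.
COVALENT_RADII: dict[str, float] = {
    "H": 0.32, "He": 0.46,
    "Li": 1.33, "Be": 1.02, "B": 0.85, "C": 0.75, "N": 0.71,
    "O": 0.63, "F": 0.64, "Ne": 0.67,
    "Na": 1.55, "Mg": 1.39, "Al": 1.26, "Si": 1.16,
    "P": 1.11, "S": 1.03, "Cl": 0.99, "Ar": 0.96,
    "K": 1.96, "Ca": 1.71, "Sc": 1.48, "Ti": 1.36,
    "V": 1.34, "Cr": 1.22, "Mn": 1.19, "Fe": 1.16,
    "Co": 1.11, "Ni": 1.10, "Cu": 1.12, "Zn": 1.18,
    "Ga": 1.24, "Ge": 1.21, "As": 1.21, "Se": 1.16,
    "Br": 1.14, "Kr": 1.17,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is absent from a lookup table."""


def normalize_symbol(symbol: str) -> str:
    """Normalize an element symbol to canonical case ("c" -> "C", "CL" -> "Cl")."""
    s = symbol.strip()
    if not s or not s.isalpha():
        raise UnknownElementError(f"invalid element symbol {symbol!r}")
    return s[0].upper() + s[1:].lower()


def atomic_mass(symbol: str) -> float:
    """Atomic mass (amu) for an element symbol; case-insensitive."""
    s = normalize_symbol(symbol)
    try:
        return ATOMIC_MASSES[s]
    except KeyError:
        raise UnknownElementError(f"no atomic mass tabulated for element {s!r}") from None


def covalent_radius(symbol: str, radii: dict[str, float] | None = None) -> float:
    """Single-bond covalent radius (Angstroem) for an element symbol.

    ``radii`` overrides the shipped table (symbols must be canonical case).
    """
    s = normalize_symbol(symbol)
    table = radii if radii is not None else COVALENT_RADII
    try:
        r = table[s]
    except KeyError:
        raise UnknownElementError(f"no covalent radius tabulated for element {s!r}") from None
    if r <= 0:
        raise ValueError(f"covalent radius for {s!r} must be positive, got {r}")
    return r
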