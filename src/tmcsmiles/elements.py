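"""Element data used for bond perception and Lewis-structure assignment.

Three per-element tables drive the pipeline:

``covalent_radius``
    Single-bond covalent radii in Å (Cordero et al. consensus values, with
    the low-spin radii for Mn/Fe/Co).  Two atoms are bonded when their
    distance is below the sum of radii plus a tolerance.

``max_valence``
    Maximum number of *neighbours* a main-group atom may have in the
    adjacency matrix.  Connectivity perception cuts bonds until every
    non-metal atom complies.  The values follow the xyz2mol valence
    convention (note the deliberately strict halogen limit of one
    neighbour, which is what shreds perchlorate into lone oxygens).

``allowed_valences``
    The list of bond-order sums a neutral-or-charged atom may adopt during
    Lewis-structure enumeration, again following xyz2mol.

``n_valence_electrons``
    Valence electron counts used both for the Hückel electron bookkeeping
    and for octet-rule formal charges.

Transition metals are exempt from all valence limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Cordero et al. covalent radii (Å); Mn/Fe/Co low spin.
_COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76,
    "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32,
    "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95,
    "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54, "Tc": 1.47, "Ru": 1.46,
    "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Ce": 2.04, "Pr": 2.03, "Nd": 2.01,
    "Pm": 1.99, "Sm": 1.98, "Eu": 1.98, "Gd": 1.96, "Tb": 1.94, "Dy": 1.92,
    "Ho": 1.92, "Er": 1.89, "Tm": 1.90, "Yb": 1.87, "Lu": 1.87,
    "Hf": 1.75, "Ta": 1.70, "W": 1.62, "Re": 1.51, "Os": 1.44, "Ir": 1.41,
    "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Tl": 1.45, "Pb": 1.46, "Bi": 1.48, "Po": 1.40, "At": 1.50,
    "Ac": 2.15, "Th": 2.06, "Pa": 2.00, "U": 1.96, "Np": 1.90, "Pu": 1.87,
}

# Maximum neighbour counts for the adjacency-matrix filter (xyz2mol
# convention: the largest entry of each element's allowed-valence list).
_MAX_VALENCE = {
    "H": 1, "B": 4, "C": 4, "N": 4, "O": 3, "F": 1,
    "Si": 4, "P": 5, "S": 6, "Cl": 1, "Ge": 4, "As": 5, "Se": 6, "Br": 1,
    "Sn": 4, "Sb": 5, "Te": 6, "I": 1,
}

# Allowed bond-order sums tried (in ascending order) during Lewis
# enumeration.
_ALLOWED_VALENCES = {
    "H": [1], "B": [3, 4], "C": [4], "N": [3, 4], "O": [1, 2, 3], "F": [1],
    "Si": [4], "P": [3, 5], "S": [2, 3, 6], "Cl": [1],
    "Ge": [4], "As": [3, 5], "Se": [2, 4, 6], "Br": [1],
    "Sn": [4], "Sb": [3, 5], "Te": [2, 4, 6], "I": [1],
}

_VALENCE_ELECTRONS = {
    "H": 1, "He": 2,
    "Li": 1, "Be": 2, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Ne": 8,
    "Na": 1, "Mg": 2, "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7, "Ar": 8,
    "K": 1, "Ca": 2, "Ga": 3, "Ge": 4, "As": 5, "Se": 6, "Br": 7, "Kr": 8,
    "Rb": 1, "Sr": 2, "In": 3, "Sn": 4, "Sb": 5, "Te": 6, "I": 7, "Xe": 8,
    "Cs": 1, "Ba": 2, "Tl": 3, "Pb": 4, "Bi": 5, "Po": 6, "At": 7,
}

# d-block elements, groups 3-12, periods 4-7.
TRANSITION_METALS = frozenset(
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Y Zr Nb Mo Tc Ru Rh Pd Ag Cd "
    "La Hf Ta W Re Os Ir Pt Au Hg "
    "Ac Rf Db Sg Bh Hs Mt Ds Rg Cn".split()
)

_KNOWN_ELEMENTS = frozenset(_COVALENT_RADIUS) | TRANSITION_METALS


def is_transition_metal(symbol: str) -> bool:
    return symbol in TRANSITION_METALS


@dataclass
class ElementTables:
    """Bundle of the per-element lookup tables, with optional overrides.

    Overrides supplied through the config replace individual entries; the
    shipped defaults cover everything the pipeline needs for ordinary
    organic and inorganic ligands.
    """

    covalent_radius: dict[str, float] = field(default_factory=dict)
    max_valence: dict[str, int] = field(default_factory=dict)
    allowed_valences: dict[str, list[int]] = field(default_factory=dict)
    n_valence_electrons: dict[str, int] = field(default_factory=dict)

    def radius(self, symbol: str) -> float:
        try:
            return self.covalent_radius.get(symbol) or _COVALENT_RADIUS[symbol]
        except KeyError:
            raise KeyError(f"no covalent radius for element {symbol!r}") from None

    def max_neighbours(self, symbol: str) -> int | None:
        """Neighbour-count cap for the AC filter; None = unconstrained."""
        if is_transition_metal(symbol):
            return None
        if symbol in self.max_valence:
            return self.max_valence[symbol]
        return _MAX_VALENCE.get(symbol)

    def valences(self, symbol: str) -> list[int]:
        if symbol in self.allowed_valences:
            return sorted(self.allowed_valences[symbol])
        if symbol in _ALLOWED_VALENCES:
            return list(_ALLOWED_VALENCES[symbol])
        raise KeyError(f"no allowed-valence list for element {symbol!r}")

    def valence_electrons(self, symbol: str) -> int:
        if symbol in self.n_valence_electrons:
            return self.n_valence_electrons[symbol]
        try:
            return _VALENCE_ELECTRONS[symbol]
        except KeyError:
            raise KeyError(f"no valence-electron count for element {symbol!r}") from None

    def knows(self, symbol: str) -> bool:
        return symbol in _KNOWN_ELEMENTS


DEFAULT_TABLES = ElementTables()
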