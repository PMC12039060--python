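"""Bond perception from Cartesian coordinates.

The adjacency matrix (AC) of a complex is perceived from interatomic
distances: atoms *i* and *j* are bonded when ``d(i,j) < r_i + r_j + tol``
with a tolerance of 0.45 Å on the covalent-radius sum.  Two repair passes
follow:

1. valence filtering — a main-group atom with more neighbours than its
   maximum valence loses its weakest bonds (longest relative to the
   covalent-radius sum) until it complies; transition metals are exempt;
2. haptic pruning — within a patch of mutually bonded metal-coordinating
   atoms, metal bonds much longer than the shortest one in the patch are
   considered artefacts of the distance criterion and cut.

Finally the complex is split into the metal and its ligands (connected
components of the metal-deleted graph); components without a metal bond
are carried along as counter-ions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .elements import ElementTables, DEFAULT_TABLES, is_transition_metal

logger = logging.getLogger(__name__)


class XYZParseError(ValueError):
    pass


class NotMononuclearError(ValueError):
    """Raised when the structure does not contain exactly one d-block atom."""


@dataclass
class XYZStructure:
    """Element symbols and Cartesian coordinates (Å) of one complex."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for el, (x, y, z) in zip(self.elements, self.coords):
            lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class CutBond:
    i: int
    j: int
    reason: str
    relative_length: float


@dataclass
class AdjacencyMatrix:
    """Symmetric 0/1 bond matrix with a provenance log of removed bonds."""

    ac: np.ndarray
    cut_log: list[CutBond] = field(default_factory=list)

    def copy(self) -> "AdjacencyMatrix":
        return AdjacencyMatrix(self.ac.copy(), list(self.cut_log))

    def degree(self, i: int) -> int:
        return int(self.ac[i].sum())

    def neighbours(self, i: int) -> list[int]:
        return [int(j) for j in np.flatnonzero(self.ac[i])]


@dataclass
class LigandFragment:
    """One connected ligand (or counter-ion) of a complex.

    ``coordinating_atoms`` are fragment-local indices of atoms bonded to
    the metal; the list is empty for counter-ions.
    """

    atom_indices: list[int]
    elements: list[str]
    coords: np.ndarray
    coordinating_atoms: list[int]
    bonds: list[tuple[int, int]]  # fragment-local

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def is_counter_ion(self) -> bool:
        return not self.coordinating_atoms


def parse_xyz(text: str) -> XYZStructure:
    """Parse a standard XYZ block (count line, comment line, atom lines)."""
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty xyz input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"malformed atom-count header: {lines[0]!r}") from None
    body = lines[2 : 2 + n]
    atom_lines = [ln for ln in body if ln.strip()]
    if len(atom_lines) != n:
        raise XYZParseError(
            f"header announces {n} atoms but {len(atom_lines)} atom lines found"
        )
    elements, coords = [], []
    for k, ln in enumerate(atom_lines):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"malformed atom line {k + 3}: {ln!r}")
        sym = parts[0].capitalize()
        if not DEFAULT_TABLES.knows(sym):
            raise XYZParseError(f"unknown element {parts[0]!r} on line {k + 3}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"bad coordinates on line {k + 3}: {ln!r}") from None
        elements.append(sym)
        coords.append(xyz)
    return XYZStructure(elements, np.array(coords))


def build_ac(
    s: XYZStructure,
    tables: ElementTables = DEFAULT_TABLES,
    tolerance: float = 0.45,
) -> AdjacencyMatrix:
    """Distance-based adjacency: bonded iff d < r_i + r_j + tolerance."""
    radii = np.array([tables.radius(el) for el in s.elements])
    dist = s.distance_matrix()
    cutoff = radii[:, None] + radii[None, :] + tolerance
    ac = (dist < cutoff).astype(np.int8)
    np.fill_diagonal(ac, 0)
    return AdjacencyMatrix(ac)


def _relative_length(s: XYZStructure, tables: ElementTables, i: int, j: int) -> float:
    d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
    return d / (tables.radius(s.elements[i]) + tables.radius(s.elements[j]))


def enforce_valence_limits(
    ac: AdjacencyMatrix,
    s: XYZStructure,
    tables: ElementTables = DEFAULT_TABLES,
) -> AdjacencyMatrix:
    """Cut the weakest bonds of over-coordinated main-group atoms.

    While any non-metal atom exceeds its maximum neighbour count, the atom
    with the largest violation is processed first and loses its bond with
    the largest distance-to-radius ratio; ties break on (relative length,
    atom index).  Metals are exempt and bonds to the metal count toward
    the ligand atom's neighbour total.
    """
    out = ac.copy()

    def violations():
        v = []
        for i, el in enumerate(s.elements):
            cap = tables.max_neighbours(el)
            if cap is None:
                continue
            excess = out.degree(i) - cap
            if excess > 0:
                v.append((excess, i))
        return v

    while True:
        v = violations()
        if not v:
            break
        _, atom = max(v, key=lambda t: (t[0], -t[1]))
        # weakest = longest bond relative to the covalent radii
        cand = [
            (_relative_length(s, tables, atom, j), j) for j in out.neighbours(atom)
        ]
        rel, j = max(cand, key=lambda t: (t[0], t[1]))
        out.ac[atom, j] = out.ac[j, atom] = 0
        out.cut_log.append(CutBond(atom, j, "valence_limit", rel))
        logger.debug("valence_limit\t%d\t%d\t%.3f", atom, j, rel)
    return out


def prune_fake_haptic(
    ac: AdjacencyMatrix,
    s: XYZStructure,
    metal_index: int,
    ratio_cutoff: float = 1.3,
) -> AdjacencyMatrix:
    """Cut spuriously perceived haptic bonds.

    Coordinating atoms that are mutually bonded form a haptic patch; a
    genuine haptic unit (e.g. η⁵-Cp) has near-equal metal distances.  A
    metal bond whose length exceeds ``ratio_cutoff`` times the patch
    minimum is an artefact and is removed.  The shortest bond of a patch
    is never cut.
    """
    out = ac.copy()
    coord = out.neighbours(metal_index)
    sub = nx.Graph()
    sub.add_nodes_from(coord)
    for a in coord:
        for b in coord:
            if a < b and out.ac[a, b]:
                sub.add_edge(a, b)
    for patch in nx.connected_components(sub):
        if len(patch) < 2:
            continue
        dists = {
            a: float(np.linalg.norm(s.coords[a] - s.coords[metal_index]))
            for a in patch
        }
        dmin = min(dists.values())
        for a in sorted(patch):
            if dists[a] > ratio_cutoff * dmin:
                out.ac[a, metal_index] = out.ac[metal_index, a] = 0
                out.cut_log.append(
                    CutBond(a, metal_index, "fake_haptic", dists[a] / dmin)
                )
                logger.debug(
                    "fake_haptic\t%d\t%d\t%.3f", a, metal_index, dists[a] / dmin
                )
    return out


def find_metal(s: XYZStructure) -> int:
    """Index of the single transition-metal atom.

    Raises :class:`NotMononuclearError` for zero or several d-block atoms.
    """
    metals = [i for i, el in enumerate(s.elements) if is_transition_metal(el)]
    if len(metals) != 1:
        raise NotMononuclearError(
            f"expected exactly one transition metal, found {len(metals)}"
        )
    return metals[0]


def split_ligands(
    ac: AdjacencyMatrix, s: XYZStructure
) -> tuple[int, list[LigandFragment]]:
    """Split into metal + ligand fragments (connected components sans metal)."""
    metal = find_metal(s)
    g = nx.Graph()
    g.add_nodes_from(range(s.n_atoms))
    for i, j in zip(*np.nonzero(np.triu(ac.ac))):
        g.add_edge(int(i), int(j))
    coordinating = set(ac.neighbours(metal))
    g.remove_node(metal)
    fragments = []
    for comp in sorted(nx.connected_components(g), key=min):
        idx = sorted(comp)
        local = {a: k for k, a in enumerate(idx)}
        bonds = [
            (local[a], local[b])
            for a in idx
            for b in ac.neighbours(a)
            if b in local and local[a] < local[b]
        ]
        fragments.append(
            LigandFragment(
                atom_indices=idx,
                elements=[s.elements[a] for a in idx],
                coords=s.coords[idx],
                coordinating_atoms=[local[a] for a in idx if a in coordinating],
                bonds=bonds,
            )
        )
    return metal, fragments
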