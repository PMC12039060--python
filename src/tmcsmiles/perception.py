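"""Lewis structures for isolated ligands by valence enumeration.

Given a ligand fragment (fixed connectivity, explicit hydrogens) and a
target integer charge, the solver loops over all combinations of allowed
per-atom valences, saturates the remaining unsaturation by incrementing
bond orders between still-unsaturated neighbours, and keeps every
assignment whose octet-rule formal charges sum to the target and whose
RDKit mol sanitizes.  Atoms left below their chosen valence pick up the
corresponding formal charge (e.g. a singly bonded oxygen becomes O⁻).

Two passes are run: one admitting neutral divalent carbon (carbenes) as a
valence state, one without.  All candidates are pooled and scored:

1. a larger aromatic system wins;
2. fewer formal charges win, but negative charges on the metal-
   coordinating atoms are not penalized;
3. remaining ties break on the canonical SMILES string.

When a carbene solution exists, ylide candidates that merely re-express
the carbene as a (C⁻, N⁺) charge pair are discarded first — the neutral
carbene is the preferred representation of such ligands.

If no charge-consistent Lewis structure exists at the requested charge,
one fallback is attempted with two electrons added (q ≥ 0) or removed
(q < 0); a second failure makes the whole complex yield no SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from rdkit import Chem

from .config import PipelineConfig, DEFAULT_CONFIG
from .connectivity import LigandFragment
from .elements import ElementTables, DEFAULT_TABLES
from .huckel import ChargeGuess

logger = logging.getLogger(__name__)

_MAX_BOND_ORDER = 3
_STATE_LIMIT = 200_000

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass
class LigandMol:
    """A solved ligand Lewis structure."""

    fragment: LigandFragment
    bond_orders: dict[tuple[int, int], int]
    formal_charges: list[int]
    charge: int
    carbene_atoms: list[int]
    mol: Chem.Mol
    canonical_smiles: str
    n_aromatic: int
    fallback_used: bool = False

    @property
    def coordinating_atoms(self) -> list[int]:
        return self.fragment.coordinating_atoms


@dataclass
class ResonanceCandidate:
    mol: LigandMol
    n_aromatic_atoms: int
    penalized_charge_count: int


class LewisFailure(Exception):
    """No sanitizable Lewis structure at the attempted charge(s)."""

    def __init__(self, fragment: LigandFragment, tried_charges: list[int]):
        self.fragment = fragment
        self.tried_charges = tried_charges
        super().__init__(
            f"no valence/charge solution for fragment at charges {tried_charges}"
        )


def _octet_formal_charge(
    sym: str, bo_sum: int, degree: int, n_val: int, allow_carbene: bool
) -> tuple[int, bool]:
    """Octet-bookkeeping formal charge; second value marks a carbene.

    A carbene is a divalent neutral carbon with two σ-bonds and a lone
    pair; a terminal doubly bonded carbon (degree 1) is not one.
    """
    if sym == "H":
        return 1 - bo_sum, False
    if sym == "B":
        return 3 - bo_sum, False
    if sym in ("P", "As", "Sb") and bo_sum == 5:
        return 0, False
    if sym in ("S", "Se", "Te") and bo_sum == 6:
        return 0, False
    if allow_carbene and sym == "C" and bo_sum == 2 and degree == 2:
        return 0, True
    return n_val - 8 + bo_sum, False


def _build_mol(
    f: LigandFragment, bo: dict[tuple[int, int], int], fc: list[int]
) -> Chem.Mol | None:
    rw = Chem.RWMol()
    for k, el in enumerate(f.elements):
        a = Chem.Atom(el)
        a.SetFormalCharge(int(fc[k]))
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for (i, j), order in bo.items():
        rw.AddBond(i, j, _BOND_TYPES[order])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _saturations(edges, deg, targets, seen, budget):
    """All maximal bond-order assignments for one valence combination.

    Starts from all-single bonds and increments orders between mutually
    unsaturated neighbours until no increment is possible; enumerates the
    distinct end states depth-first in canonical edge order.
    """
    n = len(deg)
    base = tuple(1 for _ in edges)

    def rem(state):
        sums = list(deg)
        for e, (i, j) in enumerate(edges):
            extra = state[e] - 1
            sums[i] += extra
            sums[j] += extra
        return [targets[k] - sums[k] for k in range(n)]

    out = []
    stack = [base]
    visited = set()
    while stack:
        if budget[0] <= 0:
            break
        budget[0] -= 1
        state = stack.pop()
        if state in visited:
            continue
        visited.add(state)
        r = rem(state)
        if any(v < 0 for v in r):
            continue
        eligible = [
            e
            for e, (i, j) in enumerate(edges)
            if state[e] < _MAX_BOND_ORDER and r[i] > 0 and r[j] > 0
        ]
        if not eligible:
            if state not in seen:
                seen.add(state)
                out.append(state)
            continue
        for e in reversed(eligible):
            nxt = list(state)
            nxt[e] += 1
            stack.append(tuple(nxt))
    return out


def _lewis_candidates(
    f: LigandFragment,
    charge: int,
    tables: ElementTables,
    allow_carbene: bool,
    cap: int,
) -> list[LigandMol]:
    """All distinct sanitizable Lewis structures at the given charge."""
    n = f.n_atoms
    if n == 1:
        # an isolated atom carries the whole charge; the electron count
        # must stay between the bare core and a full octet (duet for H)
        n_electrons = tables.valence_electrons(f.elements[0]) - charge
        shell = 2 if f.elements[0] == "H" else 8
        if not 0 <= n_electrons <= shell:
            return []
        bo: dict[tuple[int, int], int] = {}
        fc = [charge]
        mol = _build_mol(f, bo, fc)
        if mol is None:
            return []
        return [
            LigandMol(f, bo, fc, charge, [], mol, Chem.MolToSmiles(mol),
                      sum(a.GetIsAromatic() for a in mol.GetAtoms()))
        ]

    edges = sorted(f.bonds)
    deg = [0] * n
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    vlists = []
    for k, el in enumerate(f.elements):
        try:
            vs = tables.valences(el)
        except KeyError:
            logger.warning("no valence list for %s; using its degree %d", el, deg[k])
            vs = [deg[k]]
        if allow_carbene and el == "C":
            vs = sorted(set(vs) | {2})
        vs = [v for v in vs if v >= deg[k]]
        if not vs:
            return []  # over-coordinated beyond every allowed valence
        vlists.append(vs)

    n_vals = [tables.valence_electrons(el) for el in f.elements]
    results: list[LigandMol] = []
    seen_states: set[tuple] = set()
    budget = [_STATE_LIMIT]
    for combo in product(*vlists):
        for state in _saturations(edges, deg, list(combo), seen_states, budget):
            bo_sum = list(deg)
            for e, (i, j) in enumerate(edges):
                bo_sum[i] += state[e] - 1
                bo_sum[j] += state[e] - 1
            fc, carbenes = [], []
            for k, el in enumerate(f.elements):
                c, is_carbene = _octet_formal_charge(
                    el, bo_sum[k], deg[k], n_vals[k], allow_carbene
                )
                fc.append(c)
                if is_carbene:
                    carbenes.append(k)
            if sum(fc) != charge:
                continue
            bo = {edges[e]: state[e] for e in range(len(edges))}
            mol = _build_mol(f, bo, fc)
            if mol is None:
                continue
            results.append(
                LigandMol(
                    f, bo, fc, charge, carbenes, mol, Chem.MolToSmiles(mol),
                    sum(a.GetIsAromatic() for a in mol.GetAtoms()),
                )
            )
            if len(results) >= cap:
                logger.warning("resonance enumeration capped at %d candidates", cap)
                return results
    if budget[0] <= 0:
        logger.warning("Lewis search state budget exhausted; enumeration truncated")
    return results


def enumerate_bond_orders(
    f: LigandFragment,
    charge: int,
    tables: ElementTables = DEFAULT_TABLES,
    allow_carbene: bool = True,
    cap: int | None = None,
) -> LigandMol | None:
    """First Lewis structure (canonical enumeration order), or None."""
    cap = cap if cap is not None else DEFAULT_CONFIG.resonance_cap
    cands = _lewis_candidates(f, charge, tables, allow_carbene, cap)
    return cands[0] if cands else None


def _pooled_candidates(
    f: LigandFragment, charge: int, tables: ElementTables, cap: int
) -> list[LigandMol]:
    """Carbene-allowed and carbene-free passes pooled, deduplicated."""
    def key(m: LigandMol):
        return (tuple(sorted(m.bond_orders.items())), tuple(m.formal_charges))

    pool = _lewis_candidates(f, charge, tables, True, cap)
    seen = {key(m) for m in pool}
    for m in _lewis_candidates(f, charge, tables, False, cap):
        if key(m) not in seen:
            seen.add(key(m))
            pool.append(m)
    return pool[:cap]


def charge_fallback(
    f: LigandFragment,
    g: ChargeGuess,
    tables: ElementTables = DEFAULT_TABLES,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LigandMol:
    """Retry enumeration once with ±2 electrons after a failure at g.q.

    Two electrons are added when q ≥ 0 and removed otherwise; a second
    failure raises :class:`LewisFailure`.
    """
    q2 = g.q - 2 if g.q >= 0 else g.q + 2
    cands = _pooled_candidates(f, q2, tables, config.resonance_cap)
    if not cands:
        raise LewisFailure(f, [g.q, q2])
    logger.info("charge fallback engaged: q %+d -> %+d", g.q, q2)
    best = select_best(cands, f.coordinating_atoms, config)
    best.fallback_used = True
    return best


def enumerate_resonance(
    m: LigandMol,
    tables: ElementTables = DEFAULT_TABLES,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ResonanceCandidate]:
    """All resonance candidates sharing m's connectivity and total charge."""
    pool = _pooled_candidates(m.fragment, m.charge, tables, config.resonance_cap)
    if m.canonical_smiles not in {c.canonical_smiles for c in pool}:
        pool.append(m)
    coord = set(m.coordinating_atoms)
    return [
        ResonanceCandidate(c, c.n_aromatic, _penalized_charges(c, coord))
        for c in pool
    ]


def _penalized_charges(m: LigandMol, coordinating: set[int]) -> int:
    count = 0
    for k, c in enumerate(m.formal_charges):
        if c == 0:
            continue
        if c < 0 and k in coordinating:
            continue
        count += 1
    return count


def score_resonance(c: ResonanceCandidate) -> tuple:
    """Ordering key: max aromatic atoms, then min penalized charges.

    Smaller keys are better; the canonical SMILES string is the stable
    deterministic tie-break.
    """
    return (-c.n_aromatic_atoms, c.penalized_charge_count, c.mol.canonical_smiles)


def _is_ylide(m: LigandMol) -> bool:
    """C⁻ directly bonded to N⁺: the charged alternative to a carbene."""
    for (i, j) in m.bond_orders:
        for a, b in ((i, j), (j, i)):
            if (
                m.fragment.elements[a] == "C"
                and m.formal_charges[a] < 0
                and m.fragment.elements[b] == "N"
                and m.formal_charges[b] > 0
            ):
                return True
    return False


def select_best(
    cands: list[LigandMol],
    coordinating_atoms: list[int],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LigandMol:
    coord = set(coordinating_atoms)
    if config.prefer_carbene and any(c.carbene_atoms for c in cands):
        kept = [c for c in cands if not _is_ylide(c)]
        if kept:
            cands = kept
    wrapped = [
        ResonanceCandidate(c, c.n_aromatic, _penalized_charges(c, coord))
        for c in cands
    ]
    return min(wrapped, key=score_resonance).mol


def select_ligand_representation(
    f: LigandFragment,
    g: ChargeGuess,
    tables: ElementTables = DEFAULT_TABLES,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LigandMol:
    """Full pipeline for one ligand: enumerate both carbene settings at the
    guessed charge (falling back once by ±2 electrons), pool all resonance
    candidates and return the best-scoring representation.

    Raises :class:`LewisFailure` when neither charge yields a solution.
    """
    cands = _pooled_candidates(f, g.q, tables, config.resonance_cap)
    if cands:
        return select_best(cands, f.coordinating_atoms, config)
    return charge_fallback(f, g, tables, config)
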