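"""Three-level SMILES agreement and descriptor profiles.

Two complex SMILES can disagree as strings yet describe the same
chemistry.  Three nested comparison levels separate the cases:

``direct``
    canonical-string equality;
``resonance_tmc``
    the canonical resonance-form sets of the two complexes intersect
    (two resonance forms of the same complex compare equal);
``disconnect_resonance``
    after deleting all metal–ligand bonds the two complexes have the
    same metal and oxidation state and their ligand multisets match
    under an optimal pairing, ligands being paired when their resonance
    sets intersect and their charges agree.  Complexes differing only in
    which atoms coordinate the metal compare equal here.

Equality is monotone: direct ⊆ resonance_tmc ⊆ disconnect_resonance.

Descriptor helpers read the metal oxidation state (= metal formal
charge under the dative-bond convention) and first-shell coordination
environments (coordinating atom plus its heavy-atom neighbours,
aromatic atoms lowercase) from SMILES lists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
from rdkit import Chem

from .elements import is_transition_metal

LEVELS = ("direct", "resonance_tmc", "disconnect_resonance")

_MAX_RESONANCE_STRUCTS = 1000


class ComparisonError(ValueError):
    pass


@dataclass
class ComparisonResult:
    level: str
    equal: bool
    detail: str = ""


def _parse(smiles: str, side: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ComparisonError(f"unparsable SMILES on {side} side: {smiles!r}")
    return mol


def _metal_index(mol: Chem.Mol) -> int | None:
    metals = [
        a.GetIdx() for a in mol.GetAtoms() if is_transition_metal(a.GetSymbol())
    ]
    return metals[0] if len(metals) == 1 else None


def _resonance_smiles(mol: Chem.Mol) -> set[str]:
    out = set()
    supplier = Chem.ResonanceMolSupplier(
        mol, Chem.KEKULE_ALL, _MAX_RESONANCE_STRUCTS
    )
    for rm in supplier:
        if rm is None:
            continue
        out.add(Chem.MolToSmiles(rm))
    out.add(Chem.MolToSmiles(mol))
    return out


def _disconnect(mol: Chem.Mol, metal: int):
    """Metal charge and ligand fragments after deleting metal bonds."""
    rw = Chem.RWMol(mol)
    metal_atom = rw.GetAtomWithIdx(metal)
    for nb in [n.GetIdx() for n in metal_atom.GetNeighbors()]:
        rw.RemoveBond(nb, metal)
    frags = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False)
    ligands = []
    for f in frags:
        try:
            Chem.SanitizeMol(f)
        except Exception:
            pass
        if f.GetNumAtoms() == 1 and is_transition_metal(
            f.GetAtomWithIdx(0).GetSymbol()
        ):
            continue
        ligands.append(f)
    return metal_atom.GetFormalCharge(), ligands


def compare(s1: str, s2: str, level: str = "direct") -> ComparisonResult:
    """Compare two complex SMILES at one agreement level."""
    if level not in LEVELS:
        raise ValueError(f"unknown comparison level {level!r}")
    m1, m2 = _parse(s1, "first"), _parse(s2, "second")
    c1, c2 = Chem.MolToSmiles(m1), Chem.MolToSmiles(m2)
    if level == "direct":
        return ComparisonResult(
            level, c1 == c2, "" if c1 == c2 else "canonical strings differ"
        )
    if c1 == c2:
        return ComparisonResult(level, True, "identical canonical SMILES")
    i1, i2 = _metal_index(m1), _metal_index(m2)
    if (i1 is None) != (i2 is None):
        return ComparisonResult(level, False, "only one side has a single metal")
    if i1 is not None and i2 is not None:
        mox1 = m1.GetAtomWithIdx(i1).GetFormalCharge()
        mox2 = m2.GetAtomWithIdx(i2).GetFormalCharge()
        if m1.GetAtomWithIdx(i1).GetSymbol() != m2.GetAtomWithIdx(i2).GetSymbol():
            return ComparisonResult(level, False, "different metals")
        if mox1 != mox2:
            return ComparisonResult(
                level, False, f"oxidation state mismatch ({mox1:+d} vs {mox2:+d})"
            )
    if level == "resonance_tmc":
        equal = bool(_resonance_smiles(m1) & _resonance_smiles(m2))
        return ComparisonResult(
            level, equal, "" if equal else "resonance sets disjoint"
        )
    # disconnect_resonance
    if i1 is None or i2 is None:
        return ComparisonResult(level, False, "need one metal on each side")
    _, ligs1 = _disconnect(m1, i1)
    _, ligs2 = _disconnect(m2, i2)
    if len(ligs1) != len(ligs2):
        return ComparisonResult(level, False, "different ligand counts")
    sets1 = [_resonance_smiles(f) for f in ligs1]
    sets2 = [_resonance_smiles(f) for f in ligs2]
    q1 = [Chem.GetFormalCharge(f) for f in ligs1]
    q2 = [Chem.GetFormalCharge(f) for f in ligs2]
    g = nx.Graph()
    g.add_nodes_from(("a", i) for i in range(len(ligs1)))
    g.add_nodes_from(("b", j) for j in range(len(ligs2)))
    for i in range(len(ligs1)):
        for j in range(len(ligs2)):
            if q1[i] == q2[j] and sets1[i] & sets2[j]:
                g.add_edge(("a", i), ("b", j))
    matching = nx.algorithms.bipartite.maximum_matching(
        g, top_nodes=[("a", i) for i in range(len(ligs1))]
    )
    matched = sum(1 for k in matching if k[0] == "a")
    equal = matched == len(ligs1)
    return ComparisonResult(
        level, equal, "" if equal else "no complete ligand pairing"
    )


def compare_all(s1: str, s2: str) -> dict[str, ComparisonResult]:
    return {lvl: compare(s1, s2, lvl) for lvl in LEVELS}


@dataclass
class OxidationStateProfile:
    counts: dict[int, int]
    flagged: list[tuple[int, int]]  # (input index, M_ox) outside [0, 10]


def oxidation_state_profile(smiles: list[str]) -> OxidationStateProfile:
    """Histogram of metal oxidation states over a SMILES list."""
    counts: Counter = Counter()
    flagged = []
    for k, s in enumerate(smiles):
        mol = _parse(s, f"input {k}")
        metal = _metal_index(mol)
        if metal is None:
            continue
        mox = mol.GetAtomWithIdx(metal).GetFormalCharge()
        counts[mox] += 1
        if mox < 0 or mox > 10:
            flagged.append((k, mox))
    return OxidationStateProfile(dict(sorted(counts.items())), flagged)


def _atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def environment_strings(mol: Chem.Mol) -> list[str]:
    """First-shell environment string per coordinating atom.

    Grammar: coordinating atom first, then its direct heavy-atom
    neighbours (metal excluded) sorted in parentheses; aromatic atoms
    lowercase; a bare label for monatomic ligands.
    """
    metal = _metal_index(mol)
    if metal is None:
        return []
    out = []
    for nb in mol.GetAtomWithIdx(metal).GetNeighbors():
        shell = sorted(
            _atom_label(x)
            for x in nb.GetNeighbors()
            if x.GetIdx() != metal and x.GetSymbol() != "H"
        )
        label = _atom_label(nb)
        out.append(f"{label}({','.join(shell)})" if shell else label)
    return sorted(out)


def coordination_environments(smiles: list[str]) -> list[tuple[str, int]]:
    """Counted environment strings over a SMILES list, most common first."""
    counts: Counter = Counter()
    for k, s in enumerate(smiles):
        counts.update(environment_strings(_parse(s, f"input {k}")))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
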