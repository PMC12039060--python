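"""Repair of raw CSD-dialect SMILES into sanitizable dative-bond SMILES.

CSD SMILES write metal–ligand bonds covalently and frequently omit the
formal charges this implies, so roughly half of them fail RDKit
sanitization (kekulization errors always involve a ligand atom bonded
to the metal; valence errors are typically uncharged hypervalent N or
B).  The fixer pipeline:

1. special cases located by shipped SMARTS patterns (versioned data
   file): metal carbenes stay neutral, terminal carbonyls become
   [C-]#[O+], metal–O and metal–N triples become O²⁻ / N³⁻ donors,
   metal-bonded pyrrole-type nitrogens become pyrrolide anions;
2. every remaining covalent metal–ligand bond becomes a dative bond;
   when the bond is judged a true covalent bond — the ligand atom needs
   it to reach its default valence — the metal charge is increased and
   the ligand atom charge decreased by the bond order;
3. hypervalent uncharged N atoms away from the metal get +1 (metal −1);
   hypervalent uncharged B atoms get −1 (metal +1);
4. sanitize and canonicalize.

Every rule moves charge in balanced pairs, so the net formal charge of
the output equals that of the input.  A structure that still fails
sanitization is reported as unfixable.  ``check_formula`` compares the
implied empirical formula (implicit hydrogens materialized) against a
reference Hill formula, catching inputs whose explicit hydrogens were
wrong to begin with.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import yaml
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .elements import is_transition_metal


def _load_patterns() -> dict:
    text = (
        resources.files("tmcsmiles").joinpath("data/csd_patterns.yaml").read_text()
    )
    return yaml.safe_load(text)


_PATTERNS = _load_patterns()
PATTERN_FILE_VERSION = _PATTERNS["version"]
_COMPILED = {
    name: Chem.MolFromSmarts(entry["smarts"])
    for name, entry in _PATTERNS["patterns"].items()
}


@dataclass
class FixReport:
    input_smiles: str
    output_smiles: str | None = None
    failure: str | None = None
    applied_rules: list[str] = field(default_factory=list)
    formula_check: str = "skipped"  # pass | fail | skipped
    charge_delta_metal: int = 0

    @property
    def ok(self) -> bool:
        return self.output_smiles is not None


def _metal_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if is_transition_metal(a.GetSymbol())]


def _bond_order(bond: Chem.Bond) -> int:
    t = bond.GetBondType()
    if t == Chem.BondType.DOUBLE:
        return 2
    if t == Chem.BondType.TRIPLE:
        return 3
    return 1  # single / aromatic / anything exotic


def _ligand_valence(atom: Chem.Atom, metal: int) -> float:
    """Bond-order sum excluding metal bonds, plus explicit hydrogens."""
    v = atom.GetNumExplicitHs()
    for bond in atom.GetBonds():
        other = bond.GetOtherAtomIdx(atom.GetIdx())
        if other == metal:
            continue
        v += bond.GetBondTypeAsDouble()
    return v


def _matches(rw: Chem.Mol, name: str) -> set[int]:
    patt = _COMPILED[name]
    if patt is None:
        return set()
    try:
        return {m[0] for m in rw.GetSubstructMatches(patt)}
    except Exception:
        return set()


def fix_csd_smiles(raw: str) -> FixReport:
    """Repair one raw CSD-style SMILES; see module docstring for rules."""
    report = FixReport(input_smiles=raw)
    mol = Chem.MolFromSmiles(raw, sanitize=False)
    if mol is None:
        report.failure = "unparsable SMILES"
        return report
    rw = Chem.RWMol(mol)
    try:
        rw.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(rw)
    except Exception as exc:
        report.failure = f"property perception failed: {exc}"
        return report
    metals = _metal_indices(rw)
    if len(metals) != 1:
        report.failure = f"expected exactly one d-block atom, found {len(metals)}"
        return report
    metal = metals[0]
    metal_atom = rw.GetAtomWithIdx(metal)
    charge0_metal = metal_atom.GetFormalCharge()
    total0 = sum(a.GetFormalCharge() for a in rw.GetAtoms())

    def make_dative(idx: int):
        rw.RemoveBond(idx, metal)
        rw.AddBond(idx, metal, Chem.BondType.DATIVE)

    carbene_hits = _matches(rw, "carbene")
    co_hits = _matches(rw, "carbon_monoxide")
    pyrrole_hits = _matches(rw, "pyrrole")

    for nb in [n.GetIdx() for n in metal_atom.GetNeighbors()]:
        bond = rw.GetBondBetweenAtoms(nb, metal)
        if bond.GetBondType() == Chem.BondType.DATIVE:
            continue
        atom = rw.GetAtomWithIdx(nb)
        order = _bond_order(bond)
        sym = atom.GetSymbol()
        # --- special cases (SMARTS-located motifs)
        if sym == "C" and nb in co_hits and atom.GetFormalCharge() == 0:
            oxy = [
                x for x in atom.GetNeighbors()
                if x.GetSymbol() == "O" and x.GetDegree() == 1
            ]
            if oxy:
                o = oxy[0]
                rw.GetBondBetweenAtoms(nb, o.GetIdx()).SetBondType(
                    Chem.BondType.TRIPLE
                )
                atom.SetFormalCharge(-1)
                o.SetFormalCharge(1)
                make_dative(nb)
                report.applied_rules.append("carbonyl_triple")
                continue
        if (
            sym == "C"
            and nb in carbene_hits
            and atom.GetFormalCharge() == 0
            and bond.GetBondType() == Chem.BondType.DOUBLE
        ):
            atom.SetNoImplicit(True)  # stays a divalent carbene, not CH2
            make_dative(nb)
            report.applied_rules.append("neutral_carbene_dative")
            continue
        if (
            sym in ("O", "N")
            and bond.GetBondType() == Chem.BondType.TRIPLE
            and atom.GetDegree() == 1
            and atom.GetFormalCharge() == 0
        ):
            delta = 2 if sym == "O" else 3
            atom.SetFormalCharge(-delta)
            metal_atom.SetFormalCharge(metal_atom.GetFormalCharge() + delta)
            make_dative(nb)
            report.applied_rules.append(
                "oxo_dative" if sym == "O" else "nitride_dative"
            )
            continue
        if sym == "N" and nb in pyrrole_hits and atom.GetFormalCharge() == 0:
            atom.SetFormalCharge(-1)
            metal_atom.SetFormalCharge(metal_atom.GetFormalCharge() + 1)
            make_dative(nb)
            report.applied_rules.append("pyrrolide_anion")
            continue
        # --- generic covalent-vs-dative judgement
        default = Chem.GetPeriodicTable().GetDefaultValence(atom.GetAtomicNum())
        if default > 0 and _ligand_valence(atom, metal) < default:
            atom.SetFormalCharge(atom.GetFormalCharge() - order)
            metal_atom.SetFormalCharge(metal_atom.GetFormalCharge() + order)
            report.applied_rules.append(
                f"covalent_to_dative(order {order}) at atom {nb}"
            )
        else:
            report.applied_rules.append(f"dative_conversion at atom {nb}")
        make_dative(nb)

    # --- hypervalent N/B away from the metal
    rw.UpdatePropertyCache(strict=False)
    for atom in rw.GetAtoms():
        if atom.GetIdx() == metal or atom.GetFormalCharge() != 0:
            continue
        v = _ligand_valence(atom, metal)
        if atom.GetSymbol() == "N" and v > 3:
            atom.SetFormalCharge(1)
            metal_atom.SetFormalCharge(metal_atom.GetFormalCharge() - 1)
            report.applied_rules.append(f"hypervalent_N at atom {atom.GetIdx()}")
        elif atom.GetSymbol() == "B" and v > 3:
            atom.SetFormalCharge(-1)
            metal_atom.SetFormalCharge(metal_atom.GetFormalCharge() + 1)
            report.applied_rules.append(f"hypervalent_B at atom {atom.GetIdx()}")

    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        report.failure = f"unsanitizable after fixes: {exc}"
        return report
    total1 = sum(a.GetFormalCharge() for a in out.GetAtoms())
    assert total1 == total0, "fixer must preserve the net formal charge"
    canonical = Chem.MolToSmiles(out)
    report.output_smiles = canonical
    report.charge_delta_metal = (
        out.GetAtomWithIdx(metal).GetFormalCharge() - charge0_metal
    )
    if not report.applied_rules and canonical != raw:
        report.applied_rules.append("canonicalized")
    return report


class FormulaError(ValueError):
    pass


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Hill-notation formula → element counts; charges are ignored."""
    body = re.sub(r"[+-]\d*$", "", formula.strip())
    counts: Counter = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(body):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {formula!r} at {body[pos:]!r}")
        if not m.group(0):
            break
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(body):
        raise FormulaError(f"malformed formula {formula!r} at {body[pos:]!r}")
    return counts


def check_formula(fixed: str, reference_formula: str):
    """Compare the formula implied by a fixed SMILES with a reference.

    Returns (ok, diff) where diff maps element → (implied − reference).
    """
    ref = parse_formula(reference_formula)
    mol = Chem.MolFromSmiles(fixed)
    if mol is None:
        raise ValueError(f"fixed SMILES does not parse: {fixed!r}")
    implied = parse_formula(rdMolDescriptors.CalcMolFormula(mol))
    diff = {
        el: implied.get(el, 0) - ref.get(el, 0)
        for el in set(implied) | set(ref)
        if implied.get(el, 0) != ref.get(el, 0)
    }
    return (not diff), diff


def input_in_scope(mol: Chem.Mol, max_heavy_atoms: int = 100) -> bool:
    """Dataset-scope predicate: no group 1/2 elements, ≤ 100 heavy atoms."""
    s_block = {
        "Li", "Na", "K", "Rb", "Cs", "Fr", "Be", "Mg", "Ca", "Sr", "Ba", "Ra",
    }
    if any(a.GetSymbol() in s_block for a in mol.GetAtoms()):
        return False
    return mol.GetNumHeavyAtoms() <= max_heavy_atoms
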