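"""Complex re-assembly, charge bookkeeping and SMILES emission.

The metal oxidation state is fixed by charge conservation,

    M_ox = Q − Σ_i q_i ,

with Q the overall charge and q_i the ligand (and counter-ion) charges.
Every metal–ligand contact of the adjacency matrix becomes a dative bond
(ligand atom → metal), so the electrons of each metal–ligand bond are
bookkept on the ligand and the metal's formal charge equals its
oxidation state.  Two graph-level normalizations run after assembly:

* sulfonate-like fix — when a neutral coordinating oxygen has a
  symmetry-equivalent non-coordinating sibling carrying the −1 charge,
  charge and bond order are swapped onto the coordinating atom;
* nitro fix — every R–NO₂ / NO₂ group is rewritten to the textbook
  nitro form (one N=O, one N–O⁻, N⁺ when trisubstituted), recomputing
  the metal formal charge so the total still equals Q.

Oxidation states below 0 or above 10 are reported as unusual but never
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .config import PipelineConfig, DEFAULT_CONFIG
from .connectivity import (
    NotMononuclearError,
    XYZParseError,
    XYZStructure,
    build_ac,
    enforce_valence_limits,
    find_metal,
    parse_xyz,
    prune_fake_haptic,
    split_ligands,
)
from .huckel import adjust_charge, huckel_charge_guess
from .perception import (
    LewisFailure,
    LigandMol,
    _pooled_candidates,
    select_best,
    select_ligand_representation,
)

logger = logging.getLogger(__name__)

#: pipeline stage identifiers used in failure reports
STAGE_PARSE = "parse"
STAGE_METAL = "metal"
STAGE_LEWIS = "lewis"
STAGE_ASSEMBLY = "assembly"
STAGE_SANITIZE = "sanitize"

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass
class TMCMol:
    """Assembled complex: RDKit mol plus charge bookkeeping."""

    mol: Chem.Mol
    metal_index: int
    metal_symbol: str
    overall_charge: int
    ligand_atom_indices: list[list[int]]
    dative_bonds: list[tuple[int, int]]  # (ligand atom, metal) complex indices
    warnings: list[str] = field(default_factory=list)

    @property
    def metal_oxidation_state(self) -> int:
        return self.mol.GetAtomWithIdx(self.metal_index).GetFormalCharge()

    @property
    def ligand_charges(self) -> list[int]:
        """Current per-ligand charges (sums of formal charges)."""
        return [
            sum(self.mol.GetAtomWithIdx(i).GetFormalCharge() for i in idxs)
            for idxs in self.ligand_atom_indices
        ]

    @property
    def total_formal_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.mol.GetAtoms())


@dataclass
class ConversionResult:
    """Outcome of one structure→SMILES conversion."""

    smiles: str | None = None
    tmc: TMCMol | None = None
    failure_stage: str | None = None
    failed_ligand: int | None = None
    message: str | None = None
    ligand_charges: list[int] = field(default_factory=list)
    m_ox: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.smiles is not None


def metal_oxidation_state(Q: int, ligand_charges: list[int]) -> int:
    """M_ox = Q − Σ q_i (values < 0 or > 10 are legal but unusual)."""
    return Q - sum(ligand_charges)


def assemble_complex(
    metal_symbol: str,
    ligands: list[LigandMol],
    Q: int,
) -> TMCMol:
    """Join metal and solved ligands with dative bonds.

    The metal formal charge is set to the oxidation state so the total
    formal charge of the complex equals Q.  Counter-ion fragments (no
    coordinating atoms) become disconnected components.
    """
    charges = [lm.charge for lm in ligands]
    m_ox = metal_oxidation_state(Q, charges)
    rw = Chem.RWMol()
    metal = Chem.Atom(metal_symbol)
    metal.SetFormalCharge(m_ox)
    metal.SetNoImplicit(True)
    metal_idx = rw.AddAtom(metal)
    dative = []
    ranges = []
    for lm in ligands:
        offset = rw.GetNumAtoms()
        ranges.append(list(range(offset, offset + lm.mol.GetNumAtoms())))
        for atom in lm.mol.GetAtoms():
            rw.AddAtom(Chem.Atom(atom))
        for bond in lm.mol.GetBonds():
            rw.AddBond(
                offset + bond.GetBeginAtomIdx(),
                offset + bond.GetEndAtomIdx(),
                bond.GetBondType(),
            )
        for local in lm.coordinating_atoms:
            rw.AddBond(offset + local, metal_idx, Chem.BondType.DATIVE)
            dative.append((offset + local, metal_idx))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    tmc = TMCMol(
        mol=mol,
        metal_index=metal_idx,
        metal_symbol=metal_symbol,
        overall_charge=Q,
        ligand_atom_indices=ranges,
        dative_bonds=dative,
    )
    if not (0 <= m_ox <= 10):
        tmc.warnings.append(f"unusual_oxidation_state: M_ox={m_ox:+d}")
    return tmc


def _is_coordinating(mol: Chem.Mol, idx: int, metal_index: int) -> bool:
    b = mol.GetBondBetweenAtoms(idx, metal_index)
    return b is not None


def _rebalance_metal(tmc: TMCMol) -> None:
    """Set the metal formal charge so the total formal charge equals Q."""
    others = sum(
        a.GetFormalCharge()
        for a in tmc.mol.GetAtoms()
        if a.GetIdx() != tmc.metal_index
    )
    tmc.mol.GetAtomWithIdx(tmc.metal_index).SetFormalCharge(
        tmc.overall_charge - others
    )


def fix_sulfonate_like(m: TMCMol) -> TMCMol:
    """Move a misplaced oxyanion charge onto the coordinating oxygen.

    For any centre Z bearing both a neutral, doubly bonded oxygen that
    coordinates the metal and a singly bonded O⁻ that does not, the
    charge and the double bond are swapped.  Idempotent; a free
    (non-coordinated) oxyanion is untouched.
    """
    rw = Chem.RWMol(m.mol)
    changed = True
    applied = False
    while changed:
        changed = False
        for z in rw.GetAtoms():
            if z.GetIdx() == m.metal_index or z.GetSymbol() == "O":
                continue
            o_coord = o_free = None
            for nb in z.GetNeighbors():
                if nb.GetSymbol() != "O":
                    continue
                bond = rw.GetBondBetweenAtoms(z.GetIdx(), nb.GetIdx())
                if (
                    o_coord is None
                    and nb.GetFormalCharge() == 0
                    and bond.GetBondType() == Chem.BondType.DOUBLE
                    and _is_coordinating(rw, nb.GetIdx(), m.metal_index)
                ):
                    o_coord = nb
                elif (
                    o_free is None
                    and nb.GetFormalCharge() == -1
                    and bond.GetBondType() == Chem.BondType.SINGLE
                    and not _is_coordinating(rw, nb.GetIdx(), m.metal_index)
                ):
                    o_free = nb
            if o_coord is not None and o_free is not None:
                rw.GetBondBetweenAtoms(z.GetIdx(), o_coord.GetIdx()).SetBondType(
                    Chem.BondType.SINGLE
                )
                rw.GetBondBetweenAtoms(z.GetIdx(), o_free.GetIdx()).SetBondType(
                    Chem.BondType.DOUBLE
                )
                o_coord.SetFormalCharge(-1)
                o_free.SetFormalCharge(0)
                changed = True
                applied = True
    if not applied:
        return m
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    out = TMCMol(
        mol, m.metal_index, m.metal_symbol, m.overall_charge,
        [list(r) for r in m.ligand_atom_indices], list(m.dative_bonds),
        list(m.warnings),
    )
    out.warnings.append("fix_sulfonate_like applied")
    return out


def _nitro_groups(mol: Chem.Mol, metal_index: int):
    """Yield (N, [O, O], [R neighbours]) for NO₂-like motifs."""
    for n in mol.GetAtoms():
        if n.GetSymbol() != "N" or n.GetIdx() == metal_index:
            continue
        os, rs = [], []
        for nb in n.GetNeighbors():
            if nb.GetIdx() == metal_index:
                continue
            # terminal O: bonded to N only (metal dative bonds aside)
            heavy = [
                x for x in nb.GetNeighbors() if x.GetIdx() != metal_index
            ]
            if nb.GetSymbol() == "O" and len(heavy) == 1:
                os.append(nb)
            else:
                rs.append(nb)
        if len(os) == 2 and len(rs) <= 1:
            yield n, os, rs


def fix_nitro(m: TMCMol) -> TMCMol:
    """Normalize every NO₂ group to the textbook nitro representation.

    Target form: one N=O (neutral O), one N–O⁻; the nitrogen is +1 when it
    carries a third substituent (R–NO₂) and neutral otherwise (nitrite).
    If a coordinating oxygen is present it receives the −1 charge.  Any
    change of the group's net charge is absorbed by the metal formal
    charge so the overall charge stays Q.  Idempotent.
    """
    rw = Chem.RWMol(m.mol)
    applied = False
    for n, os_, rs in _nitro_groups(rw, m.metal_index):
        target_n_charge = 1 if rs else 0
        # pick the O that carries the charge: a coordinating O wins
        coord = [o for o in os_ if _is_coordinating(rw, o.GetIdx(), m.metal_index)]
        o_minus = coord[0] if coord else os_[0]
        o_double = os_[1] if o_minus is os_[0] else os_[0]
        b_minus = rw.GetBondBetweenAtoms(n.GetIdx(), o_minus.GetIdx())
        b_double = rw.GetBondBetweenAtoms(n.GetIdx(), o_double.GetIdx())
        already = (
            n.GetFormalCharge() == target_n_charge
            and o_minus.GetFormalCharge() == -1
            and o_double.GetFormalCharge() == 0
            and b_minus.GetBondType() == Chem.BondType.SINGLE
            and b_double.GetBondType() == Chem.BondType.DOUBLE
        )
        # also accept the mirrored assignment when neither O coordinates
        mirrored = (
            not coord
            and n.GetFormalCharge() == target_n_charge
            and o_minus.GetFormalCharge() == 0
            and o_double.GetFormalCharge() == -1
            and b_minus.GetBondType() == Chem.BondType.DOUBLE
            and b_double.GetBondType() == Chem.BondType.SINGLE
        )
        if already or mirrored:
            continue
        n.SetFormalCharge(target_n_charge)
        o_minus.SetFormalCharge(-1)
        o_double.SetFormalCharge(0)
        b_minus.SetBondType(Chem.BondType.SINGLE)
        b_double.SetBondType(Chem.BondType.DOUBLE)
        applied = True
    if not applied:
        return m
    mol = rw.GetMol()
    out = TMCMol(
        mol, m.metal_index, m.metal_symbol, m.overall_charge,
        [list(r) for r in m.ligand_atom_indices], list(m.dative_bonds),
        list(m.warnings),
    )
    _rebalance_metal(out)
    Chem.SanitizeMol(out.mol)
    out.warnings.append("fix_nitro applied")
    if not (0 <= out.metal_oxidation_state <= 10):
        out.warnings.append(
            f"unusual_oxidation_state: M_ox={out.metal_oxidation_state:+d}"
        )
    return out


def to_smiles(m: TMCMol) -> str:
    """Canonical SMILES with dative metal–ligand bonds, hydrogens folded in.

    Raises on sanitization failure (the complex then yields no SMILES).
    """
    mol = Chem.RWMol(m.mol)
    Chem.SanitizeMol(mol)
    stripped = Chem.RemoveHs(mol)
    return Chem.MolToSmiles(stripped)


def _perceive(s: XYZStructure, config: PipelineConfig):
    tables = config.tables()
    ac = build_ac(s, tables, config.tolerance)
    ac = enforce_valence_limits(ac, s, tables)
    metal = find_metal(s)
    ac = prune_fake_haptic(ac, s, metal, config.ratio_cutoff)
    metal, fragments = split_ligands(ac, s)
    return tables, ac, metal, fragments


def _read_xyz_input(xyz) -> str:
    if isinstance(xyz, Path):
        return xyz.read_text()
    if isinstance(xyz, str) and "\n" not in xyz and Path(xyz).exists():
        return Path(xyz).read_text()
    return xyz


def xyz_to_smiles(
    xyz, Q: int, config: PipelineConfig = DEFAULT_CONFIG
) -> ConversionResult:
    """Full pipeline: xyz text/path + overall charge → canonical SMILES."""
    result = ConversionResult()
    try:
        s = parse_xyz(_read_xyz_input(xyz))
    except XYZParseError as exc:
        result.failure_stage, result.message = STAGE_PARSE, str(exc)
        return result
    try:
        tables, ac, metal, fragments = _perceive(s, config)
    except NotMononuclearError as exc:
        result.failure_stage, result.message = STAGE_METAL, str(exc)
        return result
    ligand_mols = []
    for k, frag in enumerate(fragments):
        guess = adjust_charge(huckel_charge_guess(frag, tables, config), config)
        for fl in guess.flags:
            result.warnings.append(f"ligand {k}: {fl}")
        try:
            lm = select_ligand_representation(frag, guess, tables, config)
        except LewisFailure as exc:
            result.failure_stage = STAGE_LEWIS
            result.failed_ligand = k
            result.message = str(exc)
            return result
        if lm.fallback_used:
            result.warnings.append(f"ligand {k}: charge_fallback")
        ligand_mols.append(lm)
    try:
        tmc = assemble_complex(s.elements[metal], ligand_mols, Q)
        tmc = fix_sulfonate_like(tmc)
        tmc = fix_nitro(tmc)
    except Exception as exc:
        result.failure_stage, result.message = STAGE_ASSEMBLY, str(exc)
        return result
    try:
        smiles = to_smiles(tmc)
    except Exception as exc:
        result.failure_stage, result.message = STAGE_SANITIZE, str(exc)
        return result
    result.smiles = smiles
    result.tmc = tmc
    result.ligand_charges = list(tmc.ligand_charges)
    result.m_ox = tmc.metal_oxidation_state
    result.warnings.extend(tmc.warnings)
    return result


def assemble_from_fixed_charges(
    xyz,
    Q: int,
    ligand_charges,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ConversionResult:
    """Pipeline variant with externally supplied ligand charges.

    ``ligand_charges`` must list one integer per perceived fragment (in
    fragment order); the Hückel guess, its adjustments and the charge
    fallback are all skipped.  Failure to solve a ligand at its fixed
    charge fails the conversion.
    """
    result = ConversionResult()
    try:
        s = parse_xyz(_read_xyz_input(xyz))
    except XYZParseError as exc:
        result.failure_stage, result.message = STAGE_PARSE, str(exc)
        return result
    try:
        tables, ac, metal, fragments = _perceive(s, config)
    except NotMononuclearError as exc:
        result.failure_stage, result.message = STAGE_METAL, str(exc)
        return result
    charges = list(ligand_charges)
    if len(charges) != len(fragments):
        raise ValueError(
            f"fixed-charge table lists {len(charges)} ligands, "
            f"but {len(fragments)} fragments were perceived"
        )
    ligand_mols = []
    for k, (frag, q) in enumerate(zip(fragments, charges)):
        cands = _pooled_candidates(frag, int(q), tables, config.resonance_cap)
        if not cands:
            result.failure_stage = STAGE_LEWIS
            result.failed_ligand = k
            result.message = f"no Lewis solution at fixed charge {q:+d}"
            return result
        ligand_mols.append(select_best(cands, frag.coordinating_atoms, config))
    try:
        tmc = assemble_complex(s.elements[metal], ligand_mols, Q)
        tmc = fix_sulfonate_like(tmc)
        tmc = fix_nitro(tmc)
        result.smiles = to_smiles(tmc)
    except Exception as exc:
        result.failure_stage, result.message = STAGE_SANITIZE, str(exc)
        return result
    result.tmc = tmc
    result.ligand_charges = list(tmc.ligand_charges)
    result.m_ox = tmc.metal_oxidation_state
    result.warnings.extend(tmc.warnings)
    return result
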