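"""Complex assembly, the two post-assembly fixes, SMILES emission and the
end-to-end drivers."""

import numpy as np
import pytest
from rdkit import Chem

from tmcsmiles.assembly import (
    STAGE_LEWIS,
    STAGE_METAL,
    STAGE_PARSE,
    assemble_complex,
    assemble_from_fixed_charges,
    fix_nitro,
    fix_sulfonate_like,
    metal_oxidation_state,
    to_smiles,
    xyz_to_smiles,
)
from tmcsmiles.connectivity import LigandFragment
from tmcsmiles.fixtures import get_fixture, make_fixture
from tmcsmiles.perception import enumerate_bond_orders


def _fragment(elements, bonds, coordinating=()):
    return LigandFragment(
        atom_indices=list(range(len(elements))),
        elements=list(elements),
        coords=np.zeros((len(elements), 3)),
        coordinating_atoms=list(coordinating),
        bonds=list(bonds),
    )


def _ammine():
    return enumerate_bond_orders(
        _fragment(["N", "H", "H", "H"], [(0, 1), (0, 2), (0, 3)],
                  coordinating=[0]),
        0,
    )


def _chloride():
    return enumerate_bond_orders(_fragment(["Cl"], [], coordinating=[0]), -1)


class TestOxidationState:
    @pytest.mark.parametrize(
        "Q, charges, expected",
        [
            (0, [-1, -1, 0, 0], 2),
            (3, [0] * 6, 3),
            (-2, [-1, -1, -1, -1], 2),
        ],
    )
    def test_charge_conservation_identity(self, Q, charges, expected):
        assert metal_oxidation_state(Q, charges) == expected


class TestAssembleComplex:
    def test_tetrachloroplatinate(self):
        tmc = assemble_complex("Pt", [_chloride() for _ in range(4)], -2)
        assert tmc.metal_oxidation_state == 2
        assert tmc.total_formal_charge == -2
        assert len(tmc.dative_bonds) == 4

    def test_bare_metal_ion(self):
        tmc = assemble_complex("Cu", [], +1)
        assert tmc.metal_oxidation_state == 1
        assert to_smiles(tmc) == "[Cu+]"

    def test_counter_ion_is_disconnected_but_counted(self):
        free_cl = enumerate_bond_orders(_fragment(["Cl"], []), -1)
        tmc = assemble_complex("Cu", [_ammine(), free_cl], 0)
        assert tmc.metal_oxidation_state == 1
        smi = to_smiles(tmc)
        assert "." in smi and "[Cl-]" in smi
        assert Chem.GetFormalCharge(Chem.MolFromSmiles(smi)) == 0

    def test_hexacarbonyl_fixture_smiles(self, suite_results):
        spec, res = suite_results["hexacarbonylchromium"]
        assert res.smiles == spec.expected.smiles
        assert res.smiles.count("<-") + res.smiles.count("->") == 6


def _nitrite_complex():
    """Co with five ammines and a nitrito-N ligand in the degenerate
    all-single-bond form the electron-rich charge guess produces."""
    no2 = enumerate_bond_orders(
        _fragment(["N", "O", "O"], [(0, 1), (0, 2)], coordinating=[0]), -3
    )
    assert no2.formal_charges == [-1, -1, -1]
    return assemble_complex("Co", [no2] + [_ammine() for _ in range(5)], +2)


class TestFixNitro:
    def test_rewrites_to_textbook_form_and_adjusts_oxidation_state(self):
        tmc = _nitrite_complex()
        assert tmc.metal_oxidation_state == 5
        fixed = fix_nitro(tmc)
        assert fixed.metal_oxidation_state == 3
        assert fixed.total_formal_charge == tmc.overall_charge
        smi = to_smiles(fixed)
        assert "[O-]" in smi and "=O" in smi

    def test_identity_without_nitro(self):
        tmc = assemble_complex("Pt", [_chloride() for _ in range(4)], -2)
        assert fix_nitro(tmc) is tmc

    def test_idempotent(self):
        fixed = fix_nitro(_nitrite_complex())
        again = fix_nitro(fixed)
        assert to_smiles(again) == to_smiles(fixed)
        assert again.metal_oxidation_state == fixed.metal_oxidation_state

    def test_two_nitro_groups_both_rewritten(self):
        no2 = lambda: enumerate_bond_orders(
            _fragment(["N", "O", "O"], [(0, 1), (0, 2)], coordinating=[0]), -3
        )
        tmc = assemble_complex(
            "Co", [no2(), no2()] + [_ammine() for _ in range(4)], +1
        )
        fixed = fix_nitro(tmc)
        assert fixed.total_formal_charge == +1
        assert fixed.metal_oxidation_state == tmc.metal_oxidation_state - 4
        assert to_smiles(fixed).count("[O-]") == 2

    def test_nitro_fix_applied_in_pipeline(self, suite_results):
        spec, res = suite_results["nitropyridinepentaamminecobalt"]
        assert any("fix_nitro" in w for w in res.warnings)
        assert res.m_ox == 3


def _defective_mesylate():
    """Mesylate Lewis structure whose charge sits on a non-coordinating O."""
    frag = _fragment(
        ["C", "S", "O", "O", "O", "H", "H", "H"],
        [(0, 1), (1, 2), (1, 3), (1, 4), (0, 5), (0, 6), (0, 7)],
        coordinating=[2],
    )
    from tmcsmiles.perception import _pooled_candidates
    from tmcsmiles.elements import DEFAULT_TABLES

    for cand in _pooled_candidates(frag, -1, DEFAULT_TABLES, 100):
        if cand.formal_charges[2] == 0 and -1 in cand.formal_charges[3:5]:
            return cand
    raise AssertionError("expected a misplaced-charge candidate")


class TestFixSulfonateLike:
    def test_charge_moved_to_coordinating_oxygen(self):
        tmc = assemble_complex(
            "Co", [_defective_mesylate()] + [_ammine() for _ in range(5)], +2
        )
        fixed = fix_sulfonate_like(tmc)
        mol = fixed.mol
        coord_o = [i for i, m in fixed.dative_bonds if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        assert len(coord_o) == 1
        assert mol.GetAtomWithIdx(coord_o[0]).GetFormalCharge() == -1
        assert fixed.total_formal_charge == +2

    def test_already_correct_is_identity(self, suite_results):
        spec, res = suite_results["mesylatopentaamminecobalt"]
        assert not any("fix_sulfonate" in w for w in res.warnings)

    def test_free_oxyanion_counter_ion_untouched(self):
        free = enumerate_bond_orders(
            _fragment(["C", "S", "O", "O", "O", "H", "H", "H"],
                      [(0, 1), (1, 2), (1, 3), (1, 4), (0, 5), (0, 6), (0, 7)]),
            -1,
        )
        tmc = assemble_complex("Cu", [_ammine(), free], +1)
        assert fix_sulfonate_like(tmc) is tmc

    def test_idempotent_and_commutes_with_nitro_fix(self):
        no2 = enumerate_bond_orders(
            _fragment(["N", "O", "O"], [(0, 1), (0, 2)], coordinating=[0]), -3
        )
        tmc1 = assemble_complex(
            "Co", [no2, _defective_mesylate()] + [_ammine() for _ in range(4)], +1
        )
        a = fix_nitro(fix_sulfonate_like(tmc1))
        b = fix_sulfonate_like(fix_nitro(tmc1))
        assert to_smiles(a) == to_smiles(b)
        assert to_smiles(fix_sulfonate_like(a)) == to_smiles(a)


class TestToSmiles:
    def test_round_trip_is_canonical(self, successful_results):
        for name, (spec, res) in successful_results.items():
            mol = Chem.MolFromSmiles(res.smiles)
            assert mol is not None, name
            assert Chem.MolToSmiles(mol) == res.smiles, name

    def test_net_charge_matches_Q(self, successful_results):
        for name, (spec, res) in successful_results.items():
            mol = Chem.MolFromSmiles(res.smiles)
            assert Chem.GetFormalCharge(mol) == spec.overall_charge, name


class TestXYZToSmiles:
    def test_malformed_xyz_fails_at_parse(self):
        res = xyz_to_smiles("2\n\nC 0 0 0\n", 0)
        assert res.failure_stage == STAGE_PARSE

    def test_metal_free_input_fails_at_metal_stage(self):
        res = xyz_to_smiles("2\n\nC 0 0 0\nO 1.2 0 0\n", 0)
        assert res.failure_stage == STAGE_METAL

    def test_borane_cage_fails_at_lewis_stage(self, suite_results):
        spec, res = suite_results["borane_cage_cobalt"]
        assert not res.ok
        assert res.failure_stage == STAGE_LEWIS

    def test_perchlorate_flags_unusual_oxidation_state(self, suite_results):
        spec, res = suite_results["perchlorate_artifact"]
        assert res.ok
        assert res.m_ox > 10
        assert any("unusual_oxidation_state" in w for w in res.warnings)


class TestFixedChargeAssembly:
    def test_agrees_with_huckel_path_for_tetrachloroplatinate(self):
        spec = get_fixture("tetrachloridoplatinate_2minus")
        xyz, exp = make_fixture(spec)
        res = assemble_from_fixed_charges(xyz, spec.overall_charge, [-1, -1, -1, -1])
        assert res.ok and res.smiles == exp.smiles

    def test_unreachable_fixed_charge_fails(self):
        spec = get_fixture("tetrachloridoplatinate_2minus")
        xyz, _ = make_fixture(spec)
        res = assemble_from_fixed_charges(xyz, spec.overall_charge, [-3, -1, -1, -1])
        assert not res.ok and res.failure_stage == STAGE_LEWIS
        assert res.failed_ligand == 0

    def test_incomplete_table_is_an_error(self):
        spec = get_fixture("tetrachloridoplatinate_2minus")
        xyz, _ = make_fixture(spec)
        with pytest.raises(ValueError, match="fragments"):
            assemble_from_fixed_charges(xyz, spec.overall_charge, [-1, -1, -1])
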