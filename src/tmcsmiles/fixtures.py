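"""Idealized toy-complex fixtures with known ground truth.

Every stage of the pipeline is testable offline against this suite of
generated complexes: each fixture carries a deterministic geometry
(idealized coordination polyhedron, typical bond lengths, recorded in
``geometry_recipe``) together with the expected conversion outcome —
ligand charges, metal oxidation state, canonical SMILES (or the failing
stage), and first-shell coordination-environment strings.

The suite covers neutral sigma-donors (ammine, carbonyl, pyridine),
anionic ligands (chloride, kappa1-acetate, mesylate), chelates
(bipyridine, acetylacetonate, acetamidinate, kappa2-acetate), an
N-heterocyclic carbene, a nitro-containing ligand exercising the NO2
normalization, a fake-haptic contact, a genuine eta5-cyclopentadienyl,
and the two documented failure modes: a kappa1-perchlorate whose strict
chlorine valence limit produces lone O2- fragments (artificially high
oxidation state) and a closo-borane cage that cannot be assigned a
Lewis structure.

Geometries are pure frozen data — no randomness, bit-stable across
platforms.  ``perturbed`` adds bounded uniform coordinate noise for
robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Expected:
    """Ground-truth record for one fixture."""

    smiles: str | None
    failure_stage: str | None
    ligand_charges: list[int]
    m_ox: int | None
    environments: dict[str, int] | None
    unusual_oxidation_state: bool = False
    nitro_fix_applied: bool = False


@dataclass
class FixtureSpec:
    name: str
    geometry_recipe: str
    overall_charge: int
    atoms: str  # "El x y z" lines
    expected: Expected
    notes: str = ""

    def xyz(self) -> str:
        lines = [ln for ln in self.atoms.splitlines() if ln.strip()]
        return f"{len(lines)}\n{self.name}: {self.geometry_recipe}\n" + "\n".join(lines) + "\n"


_FIXTURES: list[FixtureSpec] = [
    FixtureSpec(
        name='hexaamminecobalt_3plus',
        geometry_recipe='octahedral, six NH3 at Co-N 2.00 A',
        overall_charge=3,
        atoms="""\
Co 0.000000 0.000000 0.000000
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064
N 0.000000 0.000000 2.000000
H 0.940000 0.000000 2.380000
H -0.470000 0.814064 2.380000
H -0.470000 -0.814064 2.380000
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000""",
        expected=Expected(
            smiles='N->[Co+3](<-N)(<-N)(<-N)(<-N)<-N',
            failure_stage=None,
            ligand_charges=[0, 0, 0, 0, 0, 0],
            m_ox=3,
            environments={'N': 6},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='tetrachloridoplatinate_2minus',
        geometry_recipe='square planar, four Cl at Pt-Cl 2.30 A',
        overall_charge=-2,
        atoms="""\
Pt 0.000000 0.000000 0.000000
Cl 2.300000 0.000000 0.000000
Cl -2.300000 0.000000 0.000000
Cl 0.000000 2.300000 0.000000
Cl 0.000000 -2.300000 0.000000""",
        expected=Expected(
            smiles='[Cl-]->[Pt+2](<-[Cl-])(<-[Cl-])<-[Cl-]',
            failure_stage=None,
            ligand_charges=[-1, -1, -1, -1],
            m_ox=2,
            environments={'Cl': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='hexacarbonylchromium',
        geometry_recipe='octahedral, six CO at Cr-C 1.91 A, C-O 1.14 A',
        overall_charge=0,
        atoms="""\
Cr 0.000000 0.000000 0.000000
C 1.910000 0.000000 0.000000
O 3.050000 0.000000 0.000000
C -1.910000 0.000000 0.000000
O -3.050000 0.000000 0.000000
C 0.000000 1.910000 0.000000
O 0.000000 3.050000 0.000000
C 0.000000 -1.910000 0.000000
O 0.000000 -3.050000 0.000000
C 0.000000 0.000000 1.910000
O 0.000000 0.000000 3.050000
C 0.000000 0.000000 -1.910000
O 0.000000 0.000000 -3.050000""",
        expected=Expected(
            smiles='[O+]#[C-]->[Cr](<-[C-]#[O+])(<-[C-]#[O+])(<-[C-]#[O+])(<-[C-]#[O+])<-[C-]#[O+]',
            failure_stage=None,
            ligand_charges=[0, 0, 0, 0, 0, 0],
            m_ox=0,
            environments={'C(O)': 6},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='trans_dipyridineplatinum_dichloride',
        geometry_recipe='square planar, trans py (Pt-N 2.02 A) and Cl (2.30 A)',
        overall_charge=0,
        atoms="""\
Pt 0.000000 0.000000 0.000000
C 4.817180 -0.000018 -0.000007
C 4.114527 0.359205 -1.145440
C 2.729657 0.343963 -1.096811
N 2.020000 0.000000 0.000000
C 2.729658 -0.343963 1.096811
C 4.114527 -0.359221 1.145433
H 5.903308 -0.000034 -0.000008
H 4.632462 0.644146 -2.054062
H 2.136251 0.616185 -1.964841
H 2.136250 -0.616182 1.964842
H 4.632469 -0.644170 2.054047
C -4.817180 -0.000018 0.000007
C -4.114527 0.359205 1.145440
C -2.729657 0.343963 1.096811
N -2.020000 0.000000 0.000000
C -2.729658 -0.343963 -1.096811
C -4.114527 -0.359221 -1.145433
H -5.903308 -0.000034 0.000008
H -4.632462 0.644146 2.054062
H -2.136251 0.616185 1.964841
H -2.136250 -0.616182 -1.964842
H -4.632469 -0.644170 -2.054047
Cl 0.000000 2.300000 0.000000
Cl 0.000000 -2.300000 0.000000""",
        expected=Expected(
            smiles='[Cl-]->[Pt+2](<-[Cl-])(<-n1ccccc1)<-n1ccccc1',
            failure_stage=None,
            ligand_charges=[0, 0, -1, -1],
            m_ox=2,
            environments={'n(c,c)': 2, 'Cl': 2},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='bipyridinenickel_dichloride',
        geometry_recipe="square planar, 2,2'-bipyridine chelate (Ni-N 2.00 A) + two Cl (2.25 A)",
        overall_charge=0,
        atoms="""\
Ni 0.000000 0.000000 0.000000
C 3.519304 -0.000006 2.521987
C 2.915992 -0.000020 3.769900
C 1.522185 -0.000003 3.860100
C 0.747145 -0.000001 2.695635
C -0.747142 -0.000004 2.695636
C -1.522180 0.000004 3.860103
C -2.915985 0.000001 3.769899
C -3.519300 0.000004 2.521989
C -2.699920 0.000009 1.411203
N -1.351518 -0.000000 1.474245
N 1.351518 -0.000000 1.474245
C 2.699919 0.000012 1.411204
H 4.597821 -0.000004 2.416310
H 3.522318 -0.000014 4.671323
H 1.074138 -0.000017 4.846111
H -1.074138 0.000005 4.846116
H -3.522322 0.000000 4.671313
H -4.597819 0.000009 2.416336
H -3.112448 0.000008 0.406604
H 3.112447 0.000015 0.406605
Cl 1.590990 0.000000 -1.590990
Cl -1.590990 0.000000 -1.590990""",
        expected=Expected(
            smiles='[Cl-]->[Ni+2]1(<-[Cl-])<-n2ccccc2-c2ccccn->12',
            failure_stage=None,
            ligand_charges=[0, -1, -1],
            m_ox=2,
            environments={'n(c,c)': 2, 'Cl': 2},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='acetatotetraamminecobalt_k1',
        geometry_recipe='octahedral (one vacant site), kappa1-acetate via O (Co-O 2.00 A) + four NH3',
        overall_charge=1,
        atoms="""\
Co 0.000000 0.000000 0.000000
C -1.260041 -0.809974 3.814863
C -0.000000 -0.811341 2.966919
O 0.888695 -1.627416 3.340283
O 0.000000 0.000000 2.000000
H -1.990228 -0.084795 3.442935
H -1.010980 -0.551069 4.848287
H -1.719202 -1.802905 3.797893
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064""",
        expected=Expected(
            smiles='CC(=O)[O-]->[Co+2](<-N)(<-N)(<-N)<-N',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0, 0],
            m_ox=2,
            environments={'O(C)': 1, 'N': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='resonance scoring places the negative charge on the coordinating O',
    ),
    FixtureSpec(
        name='acetatotetraamminecobalt_k2',
        geometry_recipe='octahedral, kappa2-acetate (Co-O 2.00 A, compressed bite 1.90 A) + four NH3',
        overall_charge=1,
        atoms="""\
Co 0.000000 0.000000 0.000000
O 0.572736 0.000000 1.916239
O 1.916239 0.000000 0.572736
C 1.840474 0.000000 1.840474
C 2.901135 0.000000 2.901135
H 3.834516 0.000000 2.505155
H 2.837495 0.814064 3.502175
H 2.837495 -0.814064 3.502175
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064""",
        expected=Expected(
            smiles='CC1=O->[Co+2](<-N)(<-N)(<-N)(<-N)<-[O-]1',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0, 0],
            m_ox=2,
            environments={'O(C)': 2, 'N': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='differs from the kappa1 fixture by one dative bond only',
    ),
    FixtureSpec(
        name='acetylacetonatotetraamminecobalt',
        geometry_recipe='octahedral, acac chelate (Co-O 1.95 A) + four NH3',
        overall_charge=2,
        atoms="""\
Co 0.000000 0.000000 0.000000
C 0.523948 -0.000000 4.235800
C 0.789828 -0.000001 2.754528
O -0.145881 0.000000 1.944536
C 2.184864 -0.000000 2.227401
C 2.583854 0.000000 0.938839
C 4.083257 0.000000 0.683742
O 1.944536 -0.000000 -0.145881
H 0.929864 0.903343 4.697312
H -0.558334 -0.000002 4.402392
H 0.929867 -0.903342 4.697313
H 2.920782 -0.000000 3.024362
H 4.390313 -0.890953 0.120783
H 4.664191 0.000001 1.614006
H 4.390313 0.890954 0.120783
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064""",
        expected=Expected(
            smiles='CC1=CC(C)=O->[Co+3](<-N)(<-N)(<-N)(<-N)<-[O-]1',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0, 0],
            m_ox=3,
            environments={'O(C)': 2, 'N': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='nhc_silver_chloride',
        geometry_recipe='linear, 1,3-dimethylimidazol-2-ylidene (Ag-C 2.10 A) + Cl (2.35 A)',
        overall_charge=0,
        atoms="""\
Ag 0.000000 0.000000 0.000000
C 2.338386 0.804353 2.423319
N 1.225338 0.008547 2.892215
C 0.674318 0.153012 4.168732
C -0.676387 0.143591 4.168732
N -1.225339 -0.008547 2.892215
C -2.349378 0.771657 2.423319
C 0.000000 0.000000 2.100000
H 2.082891 1.869540 2.394581
H 3.204324 0.674458 3.081094
H 2.635607 0.491370 1.416800
H 1.330073 0.319928 5.011146
H -1.334406 0.301343 5.011146
H -2.108757 1.840304 2.394573
H -3.213417 0.629711 3.081103
H -2.642210 0.454555 1.416804
Cl 0.000000 0.000000 -2.350000""",
        expected=Expected(
            smiles='CN1C=CN(C)[C]1->[Ag+]<-[Cl-]',
            failure_stage=None,
            ligand_charges=[0, -1],
            m_ox=1,
            environments={'C(N,N)': 1, 'Cl': 1},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='neutral carbene representation preferred over the N+/C- ylide',
    ),
    FixtureSpec(
        name='nitropyridinepentaamminecobalt',
        geometry_recipe='octahedral, 3-nitropyridine via ring N (Co-N 2.00 A) + five NH3',
        overall_charge=3,
        atoms="""\
Co 0.000000 0.000000 0.000000
O 2.934156 -1.911830 4.098275
N 2.071569 -1.349695 4.786995
O 2.057178 -1.340188 6.026021
C 0.999197 -0.651010 4.094818
C -0.008897 0.005803 4.805225
C -1.012663 0.659792 4.093410
C -0.966574 0.629761 2.706900
N 0.000000 0.000000 2.000000
C 0.969204 -0.631475 2.708824
H -0.025094 0.016355 5.892383
H -1.813607 1.181635 4.607026
H -1.727843 1.125756 2.109916
H 1.723712 -1.123069 2.099659
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000""",
        expected=Expected(
            smiles='N->[Co+3](<-N)(<-N)(<-N)(<-N)<-n1cccc([N+](=O)[O-])c1',
            failure_stage=None,
            ligand_charges=[0, 0, 0, 0, 0, 0],
            m_ox=3,
            environments={'n(c,c)': 1, 'N': 5},
            unusual_oxidation_state=False,
            nitro_fix_applied=True,
        ),
        notes='Huckel assigns the nitro ligand -2; the nitro fix restores the neutral group and lowers M_ox from +5 to +3',
    ),
    FixtureSpec(
        name='mesylatopentaamminecobalt',
        geometry_recipe='octahedral, methanesulfonate via one O (Co-O 2.00 A) + five NH3',
        overall_charge=2,
        atoms="""\
Co 0.000000 0.000000 0.000000
C -1.720649 -1.110528 3.496112
S 0.000000 -0.939258 3.119364
O 0.559452 -0.418580 4.364792
O 0.400753 -2.303617 2.783058
O 0.000000 0.000000 2.000000
H -1.831426 -1.803429 4.332994
H -2.237572 -1.499552 2.616222
H -2.122361 -0.131068 3.764516
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000""",
        expected=Expected(
            smiles='CS(=O)(=O)[O-]->[Co+3](<-N)(<-N)(<-N)(<-N)<-N',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0, 0, 0],
            m_ox=3,
            environments={'O(S)': 1, 'N': 5},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='acetamidinatotetraammineiron',
        geometry_recipe='octahedral, kappa2-acetamidinate (Fe-N 2.05 A, compressed bite 1.90 A) + four NH3',
        overall_charge=1,
        atoms="""\
Fe 0.000000 0.000000 0.000000
N 0.612772 0.000000 1.956275
N 1.956275 0.000000 0.612772
C 1.942703 0.000000 1.942703
C 3.003363 0.000000 3.003363
H 0.018945 0.000000 2.773263
H 2.773263 0.000000 0.018945
H 3.936744 0.000000 2.607383
H 2.939723 0.814064 3.604404
H 2.939723 -0.814064 3.604404
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064""",
        expected=Expected(
            smiles='CC1=N->[Fe+2](<-N)(<-N)(<-N)(<-N)<-[NH-]1',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0, 0],
            m_ox=2,
            environments={'N(C)': 2, 'N': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
    ),
    FixtureSpec(
        name='tilted_pyridine_zirconium_tetrachloride',
        geometry_recipe='pyridine tilted so an ortho C sits 2.85 A from Zr (fake haptic contact) + four Cl (2.35 A)',
        overall_charge=0,
        atoms="""\
Zr 0.000000 0.000000 0.000000
C 0.000007 -1.137732 4.605344
C 1.145440 -0.523771 4.109548
C 1.096811 0.025582 2.838207
N 0.000000 0.000000 2.050000
C -1.096811 -0.602869 2.558402
C -1.145433 -1.180086 3.817338
H 0.000008 -1.579514 5.597564
H 2.054062 -0.474127 4.698600
H 1.964841 0.515630 2.406826
H -1.964842 -0.610193 1.905576
H -2.054047 -1.651066 4.174602
Cl 2.350000 0.000000 0.000000
Cl -2.350000 0.000000 0.000000
Cl 0.000000 2.350000 0.000000
Cl 0.000000 -2.350000 0.000000""",
        expected=Expected(
            smiles='[Cl-]->[Zr+4](<-[Cl-])(<-[Cl-])(<-[Cl-])<-n1ccccc1',
            failure_stage=None,
            ligand_charges=[0, -1, -1, -1, -1],
            m_ox=4,
            environments={'n(c,c)': 1, 'Cl': 4},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='haptic pruning must cut the long ortho-C-Zr contact and keep the N bond',
    ),
    FixtureSpec(
        name='cyclopentadienylmanganese_tricarbonyl',
        geometry_recipe='eta5-Cp (Mn-C 2.14 A) + three CO (Mn-C 1.80 A) piano stool',
        overall_charge=0,
        atoms="""\
Mn 0.000000 0.000000 0.000000
C 1.210000 0.000000 1.765078
C 0.373911 1.150778 1.765078
C -0.978911 0.711220 1.765078
C -0.978911 -0.711220 1.765078
C 0.373911 -1.150778 1.765078
H 2.290000 0.000000 1.865078
H 0.707649 2.177919 1.865078
H -1.852649 1.346028 1.865078
H -1.852649 -1.346028 1.865078
H 0.707649 -2.177919 1.865078
C 1.408619 0.435737 -1.032438
O 2.300744 0.711703 -1.686315
C -1.081668 1.002031 -1.032438
O -1.766725 1.636651 -1.686315
C -0.326950 -1.437768 -1.032438
O -0.534019 -2.348354 -1.686315""",
        expected=Expected(
            smiles='[O+]#[C-]->[Mn+]1234(<-[C-]#[O+])(<-[C-]#[O+])<-c5c->1c->2[cH-]->3c->45',
            failure_stage=None,
            ligand_charges=[-1, 0, 0, 0],
            m_ox=1,
            environments={'c(c,c)': 5, 'C(O)': 3},
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='genuine eta5 patch: five near-equal Mn-C distances survive pruning',
    ),
    FixtureSpec(
        name='perchlorate_artifact',
        geometry_recipe='trans pair of kappa1-perchlorates (Co-O 2.00 A, elongated Cl-O(coord) 1.50 A) + four NH3',
        overall_charge=1,
        atoms="""\
Co 0.000000 0.000000 0.000000
O 0.000000 0.000000 2.000000
Cl 1.149067 0.000000 2.964181
O 0.648270 0.000000 4.303623
O 1.947965 -1.167383 2.754707
O 1.947965 1.167383 2.754707
O 0.000000 0.000000 -2.000000
Cl -1.149067 0.000000 -2.964181
O -0.648270 0.000000 -4.303623
O -1.947965 -1.167383 -2.754707
O -1.947965 1.167383 -2.754707
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064""",
        expected=Expected(
            smiles='N->[Co+15](<-N)(<-N)(<-N)(<-[O-2])<-[O-2].[O-2].[O-2].[O-2].[O-2].[O-]Cl.[O-]Cl',
            failure_stage=None,
            ligand_charges=[-2, -1, -2, -2, -2, -1, -2, -2, 0, 0, 0, 0],
            m_ox=15,
            environments={'N': 4, 'O': 2},
            unusual_oxidation_state=True,
            nitro_fix_applied=False,
        ),
        notes='the strict Cl neighbour limit shreds ClO4- into lone O2- fragments, inflating M_ox',
    ),
    FixtureSpec(
        name='borane_cage_cobalt',
        geometry_recipe='closo-B6H6 octahedral cage (B-B 1.72 A) facing Co at 2.20 A + five NH3',
        overall_charge=0,
        atoms="""\
Co 0.000000 0.000000 0.000000
B 1.216224 0.000000 3.416224
B -1.216224 0.000000 3.416224
B 0.000000 1.216224 3.416224
B 0.000000 -1.216224 3.416224
B 0.000000 0.000000 4.632447
B 0.000000 0.000000 2.200000
H 2.406224 0.000000 3.416224
H -2.406224 0.000000 3.416224
H 0.000000 2.406224 3.416224
H 0.000000 -2.406224 3.416224
H 0.000000 0.000000 5.822447
H 0.000000 0.000000 1.010000
N 2.000000 0.000000 0.000000
H 2.380000 0.000000 -0.940000
H 2.380000 0.814064 0.470000
H 2.380000 -0.814064 0.470000
N -2.000000 0.000000 0.000000
H -2.380000 0.000000 0.940000
H -2.380000 0.814064 -0.470000
H -2.380000 -0.814064 -0.470000
N 0.000000 2.000000 0.000000
H 0.940000 2.380000 0.000000
H -0.470000 2.380000 -0.814064
H -0.470000 2.380000 0.814064
N 0.000000 -2.000000 0.000000
H 0.940000 -2.380000 0.000000
H -0.470000 -2.380000 0.814064
H -0.470000 -2.380000 -0.814064
N 0.000000 0.000000 -2.000000
H -0.940000 0.000000 -2.380000
H 0.470000 0.814064 -2.380000
H 0.470000 -0.814064 -2.380000""",
        expected=Expected(
            smiles=None,
            failure_stage='lewis',
            ligand_charges=[],
            m_ox=None,
            environments=None,
            unusual_oxidation_state=False,
            nitro_fix_applied=False,
        ),
        notes='cage boron valences cannot be satisfied; conversion must fail at the Lewis stage',
    ),
]

def fixture_suite() -> list[FixtureSpec]:
    """All fixtures, in a fixed deterministic order."""
    return list(_FIXTURES)


def get_fixture(name: str) -> FixtureSpec:
    for f in _FIXTURES:
        if f.name == name:
            return f
    raise KeyError(f"unknown fixture {name!r}")


def make_fixture(spec: FixtureSpec) -> tuple[str, Expected]:
    """(xyz text, expected record) for one fixture."""
    return spec.xyz(), spec.expected


def perturbed(spec: FixtureSpec, scale: float = 0.03, seed: int = 0) -> str:
    """XYZ text with uniform coordinate noise in [-scale, +scale] Å."""
    rng = np.random.RandomState(seed)
    lines = [ln.split() for ln in spec.atoms.splitlines() if ln.strip()]
    out = [str(len(lines)), f"{spec.name} (noise {scale} A, seed {seed})"]
    for parts in lines:
        xyz = np.array([float(v) for v in parts[1:4]])
        xyz = xyz + rng.uniform(-scale, scale, 3)
        out.append(f"{parts[0]} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    return "\n".join(out) + "\n"


def write_fixtures(directory) -> Path:
    """Write every fixture as .xyz plus an expected.tsv summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["name\tcharge\texpected"]
    for f in _FIXTURES:
        (directory / f"{f.name}.xyz").write_text(f.xyz())
        exp = f.expected.smiles if f.expected.smiles else f"FAILED:{f.expected.failure_stage}"
        rows.append(f"{f.name}\t{f.overall_charge}\t{exp}")
    (directory / "expected.tsv").write_text("\n".join(rows) + "\n")
    return directory
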