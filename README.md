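# tmcsmiles

Structure→SMILES conversion for mononuclear transition metal complexes
(TMCs).

SMILES strings for organic molecules are a solved problem; for TMCs they
are not. Metal–ligand bonding does not fit ordinary valence rules, metals
take many oxidation states, and the SMILES deposited in crystallographic
databases are frequently not even parseable by RDKit. `tmcsmiles`
converts a TMC from its Cartesian coordinates and overall charge `Q`
into a canonical, RDKit-parsable SMILES in which every metal–ligand bond
is dative (written `->`/`<-`), ligand charges are explicit, and the metal
formal charge equals its oxidation state. It is intended for people
building TMC datasets, descriptors or machine-learning inputs from
structural data.

## Method

Starting from an xyz block and the overall charge `Q`:

1. **Connectivity.** Atoms *i*, *j* are bonded when
   `d(i,j) < r_i + r_j + 0.45 Å` (covalent radii). Main-group atoms that
   exceed their maximum valence lose their longest bonds relative to the
   radius sum; spurious "haptic" metal contacts much longer than their
   patch neighbours are pruned.
2. **Ligand charges.** Each ligand is isolated and an extended Hückel
   calculation gives its orbital energies `E(ψ_k)`. The charge guess is

   `q = Σ_i V_i − 2·#{ψ_k : E(ψ_k) < E_C}`

   with `V_i` the valence-electron counts and the occupancy cutoff `E_C`
   at 10 eV binding energy (orbitals below −10 eV doubly filled).
   Implausible guesses are corrected iteratively: a positive `q` with a
   LUMO below −9 eV gains electron pairs; `q ≤ −2` with a HOMO above
   −10.2 eV loses them.
3. **Lewis structures.** Bond orders and formal charges for each ligand
   are found by enumerating allowed per-atom valences over the fixed
   connectivity (with one ±2-electron fallback). All resonance
   candidates are scored: larger aromatic systems win, then fewer formal
   charges — negative charges on metal-coordinating atoms are free — and
   a neutral carbene beats its zwitterionic equivalent.
4. **Assembly.** The metal oxidation state is `M_ox = Q − Σ q_i`; metal
   and ligands are rejoined with dative bonds, sulfonate-like misplaced
   charges and NO₂ groups are normalized, and the canonical SMILES is
   emitted. Carbonyls come out in their triple-bond form `[C-]#[O+]`.

Companion tools repair raw CSD-dialect SMILES (covalent metal bonds,
missing charges, hypervalent N/B) into the same dative convention, and
compare SMILES at three nested levels — as strings, as resonance sets,
and ligand-by-ligand after disconnecting the metal.

## Worked example

```python
from tmcsmiles import xyz_to_smiles
from tmcsmiles.fixtures import get_fixture, make_fixture

xyz_text, _ = make_fixture(get_fixture("hexaamminecobalt_3plus"))
result = xyz_to_smiles(xyz_text, Q=3)
print(result.smiles)          # N->[Co+3](<-N)(<-N)(<-N)(<-N)<-N
print(result.ligand_charges)  # [0, 0, 0, 0, 0, 0]
print(result.m_ox)            # 3
```

Six neutral ammines leave the entire overall charge on the metal:
`M_ox = Q − Σ q_i = +3`, which appears directly as the cobalt formal
charge in the SMILES. For an anionic-ligand case,
`examples/convert_structure.py` and its siblings in `examples/` each run
one capability end to end and print what the numbers mean; the
`tmc-smiles` console command exposes the same operations from a shell
(`convert`, `fix-csd`, `compare`, `profile`, `fixtures`, `batch`).

A conversion can fail honestly: a closo-borane cage has no valid Lewis
structure under single-centre valence rules and is reported as
`FAILED:lewis`, and a κ¹-perchlorate is shredded by the strict chlorine
valence limit into lone O²⁻ fragments, producing a flagged, artificially
high oxidation state. Both behaviours are part of the shipped fixture
suite.

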