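# Methods

This note records the model behind `tmcsmiles`, the parameters that
matter, the design decisions taken where the procedure is genuinely
open, and what the shipped test suite does and does not demonstrate.

## Bond perception

The adjacency matrix (AC) is perceived from interatomic distances: a
bond exists when `d < r_i + r_j + tol` with `tol = 0.45 Å` (config
`tolerance`) on Cordero-type covalent radii (low-spin values for Mn, Fe,
Co). Geometry is never rejected at this stage.

Two repair passes follow.

**Valence filtering.** Main-group atoms have a maximum neighbour count
(H 1, B 4, C 4, N 4, O 3, F 1, Si 4, P 5, S 6, halogens 1 — the largest
entry of each element's allowed-valence list; transition metals are
exempt, and metal bonds count toward the ligand atom's total). While any
atom exceeds its cap, the atom with the largest violation loses its bond
with the largest ratio `d/(r_i+r_j)`; ties break on (ratio, atom index).
The strict halogen limit is deliberate: it is what dismantles a
perceived ClO₄ unit into a Cl–O fragment plus lone oxygens, reproducing
the known perchlorate failure mode (see *Limitations*). The same
"weakest bond" heuristic is why bridging hydrides cannot be described:
the longer B–H(bridge) contact is always cut.

**Haptic pruning.** Coordinating atoms that are mutually bonded form a
haptic patch. In a genuine ηⁿ unit all metal distances are similar;
an artefact of the distance criterion shows up as one patch member much
further from the metal. A patch bond is cut when its metal distance
exceeds `ratio_cutoff` (default 1.3) times the patch minimum; the
shortest bond of a patch is never cut. The threshold is a package
choice — "much longer" has no canonical value — and every cut is logged.
Pruning runs after valence filtering.

## Ligand charge from extended Hückel occupancies

Each metal-deleted connected component is a ligand (components without a
metal bond are counter-ions and are treated identically). Orbital
energies come from YAeHMOP through RDKit's `rdEHTTools`; the engine
identity is logged. The charge guess doubly fills every orbital below
the cutoff:

    q = Σ V_i − 2·#{k : E(ψ_k) < −E_C},   E_C = 10 eV.

Energies of bound orbitals are negative in this convention, so the
occupancy boundary sits at −10 eV — between the frontier thresholds
below, which is the only reading under which the published rule set is
self-consistent (a "+10 eV" boundary would fill antibonding orbitals and
make the frontier rules meaningless).

Two iterative corrections re-read the *fixed* orbital ladder at the new
filling level (nothing is recomputed):

* `q > 0` with LUMO < −9 eV → add an electron pair (q −= 2);
* `q ≤ −2` with HOMO > −10.2 eV → remove a pair (q += 2);

capped at 4 steps per direction; a direction reversal stops the loop and
is flagged (with fixed thresholds the two rules cannot actually
alternate, so the guard is a pure safety net). Odd electron counts give
odd charges — radical ligands exist — and are flagged. If the Hückel
engine fails outright the charge falls back to electron-count parity (0
or −1) with a logged warning, never a crash.

## Lewis structures by valence enumeration

For a ligand with fixed connectivity and target charge `q`, the solver
iterates over all combinations of allowed per-atom valences (ascending,
xyz2mol-style lists: C [4], N [3,4], O [1,2,3], S [2,3,6], P [3,5],
B [3,4], halogens [1] …), saturates remaining unsaturation by
incrementing bond orders (≤ 3) between mutually unsaturated neighbours
in canonical edge order, and keeps every maximal assignment whose
octet-bookkeeping formal charges (`V − 8 + bond-order sum`, with H/B and
hypervalent-P/S special cases) sum to `q` and whose RDKit mol sanitizes.
Atoms left below their valence pick up the corresponding charge (a
singly bonded O is O⁻). A single-atom fragment carries the whole charge,
bounded by an empty-to-full valence shell (duet for H). The depth-first
search deduplicates states and carries a global state budget (200 000)
plus a candidate cap (`resonance_cap`, 500); hitting either is logged.

Two passes run: one admitting a neutral divalent carbene as a carbon
state (exactly two σ-neighbours plus a lone pair — a terminal
doubly bonded C is *not* a carbene), one without. If neither pass solves
at `q`, one fallback retries at `q−2` (for `q ≥ 0`) or `q+2`; a second
failure aborts the complex with a `lewis`-stage report.

**Scoring.** Pooled candidates are ranked by (1) more aromatic atoms
(RDKit default aromaticity model), (2) fewer formal charges, where
negative charges on metal-coordinating atoms do not count, (3) canonical
SMILES string as the deterministic tie-break. One targeted filter
precedes the ranking: when a carbene solution exists, ylide candidates —
a C⁻ directly bonded to an N⁺ — are discarded (config
`prefer_carbene`). This is required because RDKit perceives the
imidazolium-2-ide ring of the zwitterionic NHC form as aromatic, so a
purely aromaticity-first ranking would always prefer the ylide over the
intended neutral carbene; the filter is deliberately narrow so that a
genuinely aromatic carbanion ligand (e.g. cyclopentadienide or phenyl,
where no carbene form exists at the same charge) is unaffected.

## Assembly, fixes, output

`M_ox = Q − Σ q_i` over all fragments including counter-ions. The
complex is rebuilt with one dative bond per (coordinating atom → metal)
contact; the metal formal charge is set to `M_ox`, so the total formal
charge equals `Q` by construction. Values outside [0, 10] are flagged as
unusual, never rejected.

Two graph normalizations run after assembly (equivalent to string-level
fixes, without a re-parse):

* **Oxyanion charge placement.** If a centre has a neutral, doubly
  bonded coordinating O and a non-coordinating singly bonded O⁻, charge
  and double bond are swapped onto the coordinating atom. Resonance
  scoring already prefers that form; the fix is the backstop for motifs
  arriving by other routes. Idempotent; free counter-ions untouched.
* **Nitro normalization.** Every N with two terminal oxygens and at most
  one further substituent is rewritten to the textbook form: one N=O,
  one N–O⁻, N⁺ if trisubstituted, N⁰ for nitrite; a coordinating O takes
  the −1. The electron-rich Hückel guess systematically hands nitro
  ligands two extra electrons (their π* orbitals sit just below the
  −10 eV boundary), producing `N(O⁻)(O⁻)` motifs; the rewrite changes the
  ligand charge, and the metal formal charge is recomputed so the total
  stays `Q` — the oxidation state moves accordingly. RDKit normalizes
  the hypervalent `N(=O)=O` spelling to the same charge-separated form,
  so this is also the canonical parse target. Idempotent, and commutes
  with the oxyanion fix.

Hydrogens are folded into atom properties and the canonical SMILES is
emitted; re-parsing and re-canonicalizing reproduces the string.
Carbonyl ligands appear as `[C-]#[O+]` donated through carbon — the
charge-separated triple-bond form the enumeration produces.

## CSD SMILES fixer

Raw CSD-dialect SMILES are parsed without sanitization. Special motifs
located by shipped SMARTS (versioned `data/csd_patterns.yaml`):
metal-carbene doubles stay neutral divalent carbenes, terminal carbonyls
become `[C-]#[O+]`, M≡O / M≡N triples become O²⁻ / N³⁻ donors,
metal-bonded pyrrole-type N becomes pyrrolide N⁻. Every remaining
covalent metal bond is judged by the ligand atom's valence: if the bond
is needed to reach the element's default valence it is a true covalent
bond and the bond order is transferred as charge (metal +b, atom −b);
otherwise it is a donation and no charge moves. Hypervalent uncharged N
(+1, metal −1) and B (−1, metal +1) are then repaired. All rules move
charge in balanced pairs — the net formal charge is invariant, asserted
at run time. Kekulization failures resolve because the metal bonds are
converted before sanitization is attempted. The formula check
materializes implicit hydrogens and diffs against a reference Hill
formula, catching structures whose explicit hydrogens were wrong to
begin with (reported, not corrected).

## Three-level comparison

`direct` compares canonical strings. `resonance_tmc` compares canonical
resonance-form sets (RDKit `ResonanceMolSupplier`, Kekulé enumeration,
capped at 1000 structures) by intersection — two resonance forms of one
complex count as equal; strict set equality would be stricter than the
way matched pairs are counted. `disconnect_resonance` deletes all metal
bonds and matches the two ligand multisets by maximum bipartite
matching, ligands pairing when their fragment charges agree and their
resonance sets intersect; the metal element and oxidation state must
agree first (an implied precondition made explicit here). Equality is
monotone across the three levels by construction, and this ordering is
asserted over every fixture pair in the tests.

Descriptor helpers read `M_ox` as the metal formal charge and build
first-shell environment strings: coordinating atom, then its sorted
heavy-atom neighbours in parentheses, lowercase for aromatic atoms;
hydrogens are excluded.

## Synthetic fixtures: what they do and do not show

The sixteen-complex suite is pure frozen data: idealized coordination
polyhedra at typical bond lengths (recorded per fixture), covering
neutral σ-donors, anionic ligands, chelates, an NHC, a nitro ligand, a
fake-haptic contact, a genuine η⁵-Cp, and two deliberate failure modes
(perchlorate → flagged M_ox +15; closo-B₆H₆ → `FAILED:lewis`). Chelate
bites are slightly compressed relative to crystal-structure values so
that only the donor atoms fall inside the bonding cutoff — at realistic
κ²-carboxylate geometry the carboxyl carbon sits within a few
hundredths of an Å of the distance criterion, an instability of the
method itself, not of the fixtures. Expected SMILES are pinned from
manual Lewis analysis of each complex; the two artifact fixtures pin
observed behaviour as regression oracles.

Passing on this suite shows the rules compose correctly and
deterministically on clean geometry with separated ligand types; it does
not show robustness to crystallographic disorder, unusual element
combinations, near-threshold bond lengths, or the long tail of ligand
chemistry in real databases. The 0.03 Å uniform-noise re-conversion test
probes only small perturbations around the idealized geometries.

## Numerical and degenerate-input choices

* Distances in Å, no periodic boundary handling; inputs are molecular.
* All enumeration orders (valence combos, edge order, cut tie-breaks)
  are fixed and documented so byte-identical reruns are guaranteed; the
  canonical-SMILES tie-break makes ligand selection invariant under atom
  relabelling.
* An isolated atom produced by bond cutting is legal everywhere
  downstream (it becomes a charged monatomic fragment).
* A bare metal ion with no ligands converts to `[M+Q]`.
* Empty ligand fragments are a caller error; Hückel-engine failure
  degrades to a parity-based charge, logged.
* Radical electron counts are not modelled; open-shell ligands are
  carried by their charge parity only.

## Known limitations

* Bridging hydrides and other 3-centre-2-electron bonds cannot be
  represented; boron-hydride clusters fail by design at the Lewis stage.
* The strict halogen neighbour limit dismantles κ¹-perchlorate (and
  would any hypervalent halogen oxyanion), inflating the apparent metal
  oxidation state; such outputs are flagged, not suppressed.
* Nitro-containing ligands rely on the post-assembly normalization to
  undo the systematic −2 bias of the Hückel occupancy count.
* Metal-centre stereochemistry is not encoded in the output SMILES.
* Aromaticity counting follows RDKit's default model; a different model
  would shift resonance selection for edge cases.
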