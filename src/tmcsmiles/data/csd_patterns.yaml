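# Special-case substructure patterns for the CSD SMILES fixer.
# Each pattern names a ligand-side motif; the fixer applies the matching
# graph rewrite when the motif atom is bonded to the transition metal.
# New special cases are additions to this file, not code changes.
version: 1
patterns:
  carbene:
    # divalent carbon double-bonded to the metal, two heteroatom/carbon
    # sigma-neighbours, no hydrogens: keep neutral, make the bond dative
    smarts: "[#6;X3;H0;+0]"
    rule: neutral_carbene_dative
  carbon_monoxide:
    # terminal carbonyl carbon: normalize to [C-]#[O+] donated via C
    smarts: "[#6;D2,D1;+0]~[#8;D1]"
    rule: carbonyl_triple
  metal_oxo_triple:
    # O triple-bonded to the metal: rewrite as O(2-) dative donor
    smarts: "[#8;D1;+0]"
    rule: oxo_dative
  metal_nitride_triple:
    # N triple-bonded to the metal: rewrite as N(3-) dative donor
    smarts: "[#7;D1;+0]"
    rule: nitride_dative
  pyrrole:
    # pyrrolide-type aromatic N bonded to the metal: anionic N donor
    smarts: "[n;r5;H0;D3,D2]"
    rule: pyrrolide_anion
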