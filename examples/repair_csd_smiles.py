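"""Repair a raw CSD-dialect SMILES into a sanitizable dative form.

CSD SMILES write metal bonds covalently and often omit the implied
charges; RDKit then refuses to kekulize or assigns impossible valences.
"""

from tmcsmiles import fix_csd_smiles

raw = "CN(C)[Pt](Cl)Cl"  # amide N drawn covalently bonded to Pt
report = fix_csd_smiles(raw)

print("raw input:  ", raw)
print("fixed:      ", report.output_smiles)
print("rules:      ", report.applied_rules)
print("metal Δq:   ", report.charge_delta_metal)
# All three metal bonds complete their ligand atom's valence, so each
# is a true covalent bond: the fixer moves one charge unit per bond
# (N and both Cl become -1, Pt becomes +3) and rewrites every metal
# bond as dative.  The net formal charge of the molecule is unchanged.
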