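"""Convert a complex from coordinates + overall charge to a SMILES.

Builds the hexaamminecobalt(III) toy geometry, runs the full pipeline
(distance-based connectivity, extended Hückel ligand charges, Lewis
enumeration, dative-bond assembly) and prints what was inferred.
"""

from tmcsmiles import xyz_to_smiles
from tmcsmiles.fixtures import get_fixture, make_fixture

spec = get_fixture("hexaamminecobalt_3plus")
xyz_text, _ = make_fixture(spec)

result = xyz_to_smiles(xyz_text, Q=spec.overall_charge)

print("input:          ", spec.geometry_recipe, f"(Q={spec.overall_charge:+d})")
print("SMILES:         ", result.smiles)
print("ligand charges: ", result.ligand_charges)
print("oxidation state:", f"+{result.m_ox}")
# Each NH3 is a neutral sigma-donor, so all six ligand charges are 0 and
# the cobalt formal charge (the '+3' in the SMILES) equals the overall
# charge: M_ox = Q - sum(q_i) = +3.  Every Co-N bond is written as a
# dative arrow, keeping the electrons on nitrogen.
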