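"""Compare two SMILES of the same complex at three agreement levels.

The two strings below are resonance forms of a monodentate acetate
complex: the negative charge sits on the coordinating oxygen in one and
on the terminal oxygen in the other.
"""

from tmcsmiles import compare_all

a = "CC(=O)[O-]->[Co+2](<-N)(<-N)(<-N)<-N"
b = "CC([O-])=O->[Co+2](<-N)(<-N)(<-N)<-N"

for level, result in compare_all(a, b).items():
    print(f"{level:22s} equal={result.equal}  {result.detail}")
# Direct string comparison fails, but the resonance-set comparison
# recognizes the two forms as the same complex, and so (a fortiori)
# does the ligand-level comparison after disconnecting the metal.
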