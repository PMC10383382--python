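"""Compute the seven modeled 2D descriptors for the study compounds.

X4A, DECC and Eig12_AEA(bo) feed the discriminant (classification)
model; PDI, MATS8m, GATS8v and QED feed the EC50 regression.  All are
computed from the hydrogen-depleted molecular graph built from SMILES.
"""

from pfasbind import descriptor_table, load_pfas24

ds = load_pfas24()
table = descriptor_table(ds)
print(table.round(4).to_string())
print()
print("PDI = McGowan volume / total VSA surface; QED in (0,1] is the")
print("drug-likeness geometric mean; X4A shrinks as chains branch/lengthen.")
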