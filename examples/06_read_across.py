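"""Similarity-weighted read-across prediction for a PFAS target.

A target compound's binary toxicity outcome is predicted from its most
similar structural analogues: the score is the similarity-weighted mean
of the analogue activities.  Here PFOA is the target and a small
neighbourhood of PFAS homologues (plus two unrelated chemicals) serves
as the source set, with MACCS substructure keys as fingerprints.
"""

from pfasbind import AnalogueSet, genra_predict, genra_validate, pfas_smiles

target = pfas_smiles("PFCA", 8)  # PFOA
analogues = [
    (pfas_smiles("PFCA", 7), 1.0, "PFHpA"),
    (pfas_smiles("PFCA", 9), 1.0, "PFNA"),
    (pfas_smiles("PFSA", 8), 1.0, "PFOS"),
    (pfas_smiles("PFSA", 6), 1.0, "PFHxS"),
    (pfas_smiles("FTCA", 6), 1.0, "6:3 FTCA"),
    (pfas_smiles("FTOH", 6), 0.0, "6:2 FTOH"),
    (pfas_smiles("FTOH", 4), 0.0, "4:2 FTOH"),
    ("c1ccccc1O", 0.0, "phenol"),
    ("CCO", 0.0, "ethanol"),
    ("ClC(Cl)C(Cl)Cl", 1.0, "tetrachloroethane"),
]
aset = AnalogueSet.from_smiles(target, analogues)

for a in sorted(aset.analogues, key=lambda a: -a.similarity):
    print(f"  {a.label:<18} similarity {a.similarity:.3f}  active {int(a.activity)}")

pred = genra_predict(aset, k=10)
print(f"\nsimilarity-weighted activity score: {pred['score']:.3f}")

val = genra_validate(aset, k=5, n_permutations=199, seed=0)
print(f"leave-one-out neighbourhood AUC: {val['auc']:.2f}, permutation p = {val['p_value']:.3f}")
# A score near 1 predicts the toxic outcome; the leave-one-out AUC and
# permutation p-value say how much the neighbourhood itself supports it.
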