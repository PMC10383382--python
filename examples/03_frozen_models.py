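"""Score the study compounds with the two frozen albumin-binding models.

The discriminant model assigns class H to scores at or below the potency
threshold; the regression model predicts EC50 in mM.  Predictions here
use this package's own descriptor values, so they track — but do not
bit-reproduce — the published per-compound predictions, whose descriptor
source cannot be regenerated.
"""

from pfasbind import descriptor_table, load_pfas24, reference_eq1, reference_eq2

ds = load_pfas24()
table = descriptor_table(ds)

# the potency threshold was never published; calibrate it as the midpoint
# of the class-mean discriminant scores on this package's descriptor values
labels = [ds[cid].observed_class_printed for cid in table.index]
eq1 = reference_eq1().calibrate_threshold(table, labels)
eq2 = reference_eq2()
print(f"calibrated potency threshold: {eq1.threshold:.3f}\n")
scores = eq1.score(table)
classes = eq1.predict(table)
ec50 = eq2.predict(table)

print(f"{'id':<4} {'score':>8} {'class':>5} {'EC50_pred/mM':>12}")
for cid, s, c, e in zip(table.index, scores, classes, ec50):
    print(f"{cid:<4} {s:8.3f} {c:>5} {e:12.2f}")
print()
print("Low discriminant scores mean high predicted binding affinity;")
print("negative EC50 predictions flag compounds outside the model's domain.")
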