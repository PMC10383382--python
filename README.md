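# pfasbind

QSAR and read-across modeling of per- and polyfluoroalkyl substance
(PFAS) binding affinity to human serum albumin (HSA).

HSA is the principal blood transport protein; PFAS that bind it
circulate longer, bioaccumulate, and displace endogenous ligands.
`pfasbind` packages an in silico analysis of 24 PFAS with measured HSA
binding (EC50, the ligand concentration at which half the protein is
bound, in mM) into a reusable library for people building or auditing
small-dataset QSAR models: computational toxicologists, cheminformatics
practitioners, and regulatory screeners of PFAS alternatives.

## What it computes

**Descriptors.** Seven 2D descriptors computed from SMILES on the
hydrogen-depleted molecular graph: the average Kier–Hall connectivity
index of order 4 (X4A), the eccentric index DECC (mean absolute
deviation of vertex eccentricities), the 12th-largest eigenvalue of the
bond-order-augmented edge adjacency matrix (Eig12_AEA(bo)), the Moran
and Geary autocorrelations at topological lag 8 (MATS8m mass-weighted,
GATS8v van-der-Waals-volume-weighted), the packing density index
PDI = Vx/SAtot (McGowan characteristic volume over total Labute VSA
surface), and the quantitative estimate of drug-likeness
QED = exp(Σ wᵢ ln dᵢ / Σ wᵢ).

**Frozen reference models.** The binding-affinity discriminant

    ΔP = −14.668 + 33.651·Eig12_AEA(bo) + 0.378·DECC + 30.405·X4A

(scores below the potency threshold → high affinity, H) and the
PLS-derived regression

    EC50 [mM] = 24.427 − 23.551·PDI − 0.862·GATS8v − 0.607·MATS8m − 4.388·QED

**Model-building machinery.** Two-class Fisher LDA (with Wilks' λ and
its F transform), OLS, NIPALS PLS1, seeded genetic-algorithm descriptor
selection, descriptor-pool pretreatment, and the exhaustive
double-cross-validation workflow for datasets too small to split
(every 3-compound validation subset enumerated, model selection by
held-out MAE, consensus predictions).

**Validation battery.** Sensitivity, specificity, precision, accuracy,
F-measure, MCC, Cohen's κ, G-means, ROC/AUROC, R², leave-one-out Q²,
MAE and MAE(95%), Roy's scaled r²ₘ metrics, a standardization-based
applicability domain, and seeded y-randomization.

**Read-across.** Similarity-weighted activity scoring
(score = Σ sᵢaᵢ / Σ sᵢ over the k nearest analogues) with leave-one-out
AUC and permutation p-value validation, using MACCS keys as the default
fingerprint.

## Worked example

```python
from pfasbind import (assign_classes, class_counts, classification_metrics,
                      confusion, load_pfas24, regression_metrics)

ds = load_pfas24()                      # 24 PFAS, SMILES rebuilt from CAS/name
classed = assign_classes(ds, threshold_mM=1.45)
print(class_counts(classed))            # {'H': 11, 'L': 13}

train = ds.subset("train")              # 16 compounds
cm = confusion([r.observed_class_printed for r in train],
               [r.predicted_class_lda for r in train])
print(cm.tp, cm.fp, cm.tn, cm.fn)       # 7 0 8 1
block = classification_metrics(cm)
print(round(block["accuracy"], 2),      # 93.75
      round(block["sensitivity"], 2),   # 87.5
      round(block["mcc"], 2))           # 0.88

binders = ds.binders()                  # 22 compounds with measured EC50
reg = regression_metrics([r.ec50_mM for r in binders],
                         [r.predicted_ec50_pls for r in binders])
print(round(reg["mae"], 3), round(reg["r2"], 3))   # 0.205 0.803
```

The class split says 11 of the 24 PFAS bind HSA at or below 1.45 mM;
the confusion block shows the discriminant model misses exactly one
high-affinity training compound (4:2 FTSA); the regression block says
the EC50 model predicts the 22 binders with a mean absolute error of
0.205 mM and explains 80% of the EC50 variance.

The scripts in `examples/` walk through each capability end to end
(dataset and class rule, descriptors, frozen models, validation
metrics, the small-dataset workflow on synthetic data, read-across,
docking-energy correlation).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full reproduction suite from the bundled compound table —
the 11 H / 13 L class split, the training and test classification metric
tables, the regression MAE and R², the frozen-model constants, and the
docking-energy correlation — then runs the seeded double-cross-validation
workflow on synthetic data of the study's shape and writes the results
JSON. A non-zero exit means a reproduction check failed.

## Scope notes

Docking itself (the source of the carried Glide energies), the
proprietary 753-descriptor pool the original feature selection ran
over, and the EPA read-across database are out of scope; see
`docs/methods.md` for what that implies about which published numbers
are and are not reproducible here.
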