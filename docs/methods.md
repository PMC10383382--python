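# Methods

## The problem and the data

24 PFAS with experimentally determined HSA binding (EC50 in mM, from
concentration–response curves; two fluorotelomer alcohols did not bind
and carry no EC50) are modeled two ways: a two-class discriminant of
high (H) versus low (L) binding affinity on all 24 compounds, and a
linear EC50 regression on the 22 binders. The class rule is
EC50 ≤ 1.45 mM → H; non-binders are L by definition.

The compound table ships with the package. The structures are encoded
from the compounds' CAS numbers and systematic names, since the source
publication prints no SMILES; every molecular formula was verified with
RDKit (PFOA → C8HF15O2, HFPO-DA → C6HF11O3, Nafion BP2 → C7H2F14O5S,
PFO3DoDA → C7HF13O5, and so on). Acids are encoded neutral
(protonated), the usual convention for 2D descriptor software. The
table carries *two* class columns: the threshold-derived class and the
class labels as printed alongside the published model. They disagree
for three borderline compounds (C3 at 1.40 mM printed L; C8 at 1.49 mM
and C11 at 1.48 mM printed H). Keeping both lets each published number
be recomputed from the inputs its authors actually used: the 11 H/13 L
split follows the threshold rule, while the published metric tables
follow the printed labels. Similarly, the published training split is
reproduced as flags (16 train / 8 test) rather than re-randomized.

## Descriptors

All topological descriptors operate on the hydrogen-depleted graph
(Dragon/alvaDesc convention); whole-molecule quantities (McGowan
volume, QED properties) include hydrogens.

* **X4A** — Kier–Hall average path connectivity of order 4:
  Σ over simple 5-vertex paths of (Π δ)^(−1/2) divided by the path
  count, δ the heavy-atom degree; 0 when no such path exists.
* **DECC** — (1/A) Σᵢ |ηᵢ − η̄| over vertex eccentricities ηᵢ
  (BFS shortest paths). Eccentricity is undefined on disconnected
  graphs, which raise. Note the exact formula behind the commercial
  implementation of this index is not published; the mean-absolute-
  deviation form is the documented classical meaning, so the frozen
  discriminant is validated structurally (constants, signs, contract),
  not numerically against the commercial descriptor values.
* **Eig12_AEA(bo)** — bonds-by-bonds adjacency matrix, off-diagonal 1
  when two bonds share an atom, diagonal holding each bond's order
  (aromatic = 1.5); eigenvalues sorted descending by algebraic value;
  the k-th largest returned, 0 when the molecule has fewer than k bonds
  (deterministic padding). Whether the commercial implementation also
  weights off-diagonal entries by bond order is not documented;
  diagonal-only augmentation is the default here.
* **MATS8m / GATS8v** — Moran I(d) and Geary c(d) at topological lag 8.
  Pairs are counted as *ordered* pairs, with Δ the ordered-pair count
  (the Geary numerator therefore divides by 2Δ); weights are atomic
  mass and Bondi-radius vdW volume, scaled relative to carbon before
  centering (Dragon convention; `scale_to_carbon=False` gives the raw
  variant). Zero is returned when no pair sits at the lag or the weight
  variance vanishes.
* **PDI = Vx/SAtot** — Vx is the McGowan characteristic volume from the
  published atomic increments minus 6.56 per bond (hydrogens included),
  divided by 100; SAtot sums RDKit's per-heavy-atom Labute VSA
  contributions.
* **QED** — the eight properties (MW, ALOGP, HBA, HBD, PSA, ROTB,
  AROM, ALERTS) come from RDKit's calculators; the asymmetric
  double-sigmoid desirabilities use the original published constants
  and are aggregated by the weighted geometric mean in-package. Unit
  weights ("QEDw,u") are the default; the published mean/max weight
  sets are selectable. The implementation agrees with RDKit's full QED
  to 1e-10 on the study compounds.

## Models

**Discriminant.** Two-class Fisher LDA: direction w = S_w⁻¹(m_L − m_H),
oriented so the H class takes lower scores — matching the frozen
model's convention that scores below the potency threshold are H. The
threshold is the midpoint of the class-mean scores. The frozen
discriminant's potency threshold was never published; it defaults to 0
and `calibrate_threshold` recomputes it from any calibration data.
Wilks' λ = det(W)/det(B+W) with F = ((1−λ)/λ)·((n−p−1)/p) on
(p, n−p−1) degrees of freedom.

**Regression.** OLS (rank-checked) and NIPALS PLS1 collapsed to an
explicit linear predictor. Descriptors are autoscaled by default
(whether the original 3-LV PLS autoscaled or only centered is not
stated; both are exposed via `scale=`). At full latent-variable rank
PLS reproduces OLS to 1e-8, and against scikit-learn's PLSRegression to
1e-8 at every rank — scikit-learn serves only as a cross-check, never
as the implementation.

**GA selection.** Seeded GA over fixed-size descriptor subsets:
tournament selection, subset-preserving crossover (shared genes kept,
remainder sampled from the symmetric difference), per-gene swap
mutation, elitism 1. Defaults (population 50, 100 generations,
crossover 0.8, mutation 0.05) are conventional small-pool settings; the
source tool's hyperparameters are not published. Fitness is
leave-one-out Q² (regression) or 1 − Wilks' λ (classification);
fixed-seed runs are bit-reproducible.

**Double cross-validation.** All C(n, 3) validation triples are
enumerated (configurable size; a seeded subsample above `max_splits`).
Per split, optional descriptor selection runs on the training part
only, a model is fitted and scored on the held-out triple. The optimal
model is the split minimizing held-out MAE, ties broken by higher
training Q² (the source tool's exact selection rule is not published;
this rule is configurable). Consensus predictions average each
compound's held-out predictions. Q²LOO uses the exact hat-matrix
identity e_loo = e/(1 − hᵢᵢ) for linear fits — verified equal to naive
refits — which is what makes GA-inside-DCV affordable.

## Validation metrics

Percentage metrics are reported on the 0–100 scale (two decimals match
the published precision; G-means one decimal). Undefined metrics (zero
denominators) are NaN plus a flag, never silently 0. The published
F-statistic row alongside the table of formulas is a generic
variance-ratio; for LDA reporting the standard Wilks-λ→F transform is
used (it matches the printed degrees of freedom 3,12), and the generic
ratio is provided as a utility. The rm² formula as printed in the
source drops a radical; the implemented form is the standard
rm² = r²(1 − √(r² − r₀²)) on vectors min–max scaled by the observed
range. MAE(95%) discards the ⌈5% n⌉ largest absolute errors; on the 22
printed predictions the published "MAE(95%)" value (0.205) equals the
*plain* MAE, so plain MAE is the reproduction target and both variants
are reported. The applicability domain is the standardization approach
(|z| > 3 SD on any descriptor → outside, per-descriptor diagnostics);
the original AD algorithm is not described, so this is an
implementation choice, as is y-randomization implemented as seeded
response permutation with refit. ROC/AUROC goes through
scikit-learn's `roc_curve` (trapezoidal, ties averaged), cross-checked
in tests against a Mann–Whitney concordant-pair count.

## Read-across

The activity score Σ sᵢaᵢ/Σ sᵢ over the k = 10 most similar analogues
is a convex combination of analogue activities (similarity ties broken
by input order). Fingerprints default to MACCS substructure keys — a
generic stand-in for the proprietary chemotype scheme the original
analysis used, which also means the original analogue sets and their
scores are not reproduction targets. Neighbourhood validation is
leave-one-out: each analogue predicted from the rest, AUROC against
true activities, permutation p-value (999 seeded permutations,
add-one correction). A single-class neighbourhood has no defined AUROC
and is flagged `undefined` — deliberately diverging from the source
report's printed "AUC = 0" for its degenerate neighbourhoods, which
conflates "no signal measurable" with "perfectly wrong".

## Synthetic data

`SyntheticSpec` defaults state the regression study's world: n = 22
compounds, a pool of 30 candidate descriptors, 4 true descriptors with
coefficients (2, −3, 1.5, −1), Gaussian noise at 10% of the noiseless
response SD, and equicorrelation ρ = 0.3 between pool columns (mild
collinearity, typical of topological descriptor pools; a pool of 30
rather than the original ~750 keeps exhaustive testing affordable
while preserving the p ≫ "true p" selection problem). The
classification generator shifts the H-class means by a stated
separation on the true descriptors with exact label balance. The PFAS
series builder constructs perfluoroalkyl carboxylic/sulfonic acids and
fluorotelomer acids/alcohols from their repeat units; it regenerates
the study structures exactly (PFCA(8) ≡ PFOA fixture entry).

What the generators do *not* emulate: real descriptor marginals are
heavy-tailed and discretely structured, not Gaussian; real EC50 noise
is not homoscedastic; homologous series induce near-perfect descriptor
collinearity. A green recovery test therefore establishes that the
selection machinery works at the stated signal-to-noise shape, not that
the published model would be re-found from scratch.

## What is and is not reproducible

Reproduced from printed information (and asserted in the test suite at
stated tolerances): the 11 H/13 L class split; the full training and
test classification metric tables (training accuracy 93.75%,
sensitivity 87.5%, specificity 100%, F-measure 93.33%, MCC 0.88,
κ 0.88, G-means 93.5; all-perfect test column); regression MAE
rounding to 0.205 mM and R² = 0.802 ± 0.002 over the 22 binders
(predictions are printed to 2 decimals, hence the band); the frozen
model constants.

Not reproducible at desk scale, carried as recorded metadata only:
Wilks' λ = 0.26 and F(3,12) = 10.45, Q²LOO = 0.691 and r²ₘ = 0.594
(all require the original descriptor values from the proprietary
descriptor software), the training AUROC 0.97 (requires unprinted
per-compound discriminant scores), docking energies and the redocking
RMSD (commercial docking stack), and the original read-across
ACT/AUC/p-values (external database). The published statement that the
training set held 9 H and 7 L compounds is inconsistent with both the
printed per-compound labels (8 H/8 L) and the printed training
sensitivity (87.5% = 7/8); the per-compound labels are treated as
authoritative. A "25 PFAS" mention elsewhere in the source is treated
as a typo for 24.

## Known limitations

Descriptor values are this package's own implementations of the named
descriptor families; where the commercial definitions are unpublished
(DECC variant, edge-adjacency augmentation details), applying the
frozen equations to these descriptor values tracks, but does not
bit-reproduce, the published per-compound predictions. The GA and DCV
defaults are choices, not recovered settings. Only two-class
classification and single-response linear regression are supported.
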