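# cytoblast

Automated identification of leukemic blasts in high-dimensional single-cell
cytometry, built around autoencoder anomaly detection.

In acute myeloid leukemia (AML), malignant blasts carry immunophenotypes that
do not occur along healthy myeloid development — aberrant CD56, abnormally low
CD45 or CD33, or asynchronous marker combinations.  Conventional practice
finds them with manual gates on one or two markers (typically a CD45low
gate).  `cytoblast` scales this to a full 23-channel panel (21 antibody
markers plus forward/side scatter): an autoencoder is trained to reconstruct
only *healthy reference cells* (remission bone marrow), so cells it
reconstructs poorly are anomalous.  The per-marker **squared reconstruction
error** (SRE) — a 23-dimensional vector per cell — feeds a binary classifier
that labels each cell healthy or blast.  The autoencoder's 4-dimensional
latent space doubles as a developmental map of myelopoiesis (early HSPC →
monoblast/myeloblast → promonocyte → monocyte) onto which predicted blasts
are projected and staged by k-nearest-neighbor voting.

The package is aimed at computational immunologists analyzing longitudinal
cytometry cohorts (diagnosis / remission / relapse), and ships a synthetic
bone-marrow simulator with complete ground truth so the entire workflow is
testable without any patient data.

## Model

For a cell with scaled marker vector `x ∈ R^23` and autoencoder
reconstruction `x̂ = g(f(x))` (encoder `f: R^23 → R^4`, mirrored decoder `g`):

- training loss: `MSE = mean_j (x_j − x̂_j)²`, plus `β·KL` for the
  variational variant (encode and reconstruct use the posterior mean, so
  features are deterministic);
- SRE feature vector: `s_j = (x_j − x̂_j)²` per marker `j`;
- preprocessing: `asinh(x/c_j)` with per-marker cofactor `c_j`, then
  per-marker min-max scaling `(x − min)/(max − min)` fitted on training data
  only and reused unclipped on held-out data.

The classifier is selected over margin-based, linear, small feed-forward and
tree-ensemble families on balanced leave-one-patient-out (LOPO) splits: each
fold holds out one patient's annotated blasts, subsampled to one remission
validation share (1/20 of the remission-test pool when 20 patients
contribute), with training blasts subsampled to the remaining 19/20.

Supporting statistics: clustering-stability selection by mean pairwise
adjusted Rand index over repeated runs; the individuality score
`p(class_i | kNN) ∝ n_NN,i / n_class_i` (inverse-class-size-corrected kNN
posterior); single-Gaussian fits to diagnosis and relapse latent encodings
whose log-density comparison flags "diagnosis-like-relapse" cells; and
diagnosis→relapse marker-positivity change accounting at a strict ±5 %
threshold.

## Worked example

```python
import cytoblast as cb

cohort = cb.simulate_cohort(n_patients=4, cells_per_sample=2000,
                            remission_patients=3, seed=11)
result = cb.run_blast_pipeline(cohort, seed=11, n_trials=3)

print(f"selected classifier family: {result.classifier.family}")
print(f"LOPO mean validation accuracy: {result.classifier.mean_val_accuracy:.3f}")
print(f"SRE classifier balanced accuracy: {result.sre_metrics['balanced_accuracy']:.3f}")
print(f"CD45low gate balanced accuracy:  {result.gate_metrics['balanced_accuracy']:.3f}")
print(f"latent kNN stage recovery: {result.stage_recovery:.3f}")
comp = result.blast_compositions["P1_diagnosis"]
print("P1 diagnosis blast composition:",
      {k: round(v, 3) for k, v in comp.fractions.items()})
```

prints

```
selected classifier family: svm
LOPO mean validation accuracy: 0.739
SRE classifier balanced accuracy: 0.998
CD45low gate balanced accuracy:  0.625
latent kNN stage recovery: 0.874
P1 diagnosis blast composition: {'early HSPC': 0.792, 'monoblast/myeloblast': 0.208, 'promonocyte': 0.0, 'monocyte': 0.0}
```

Reading the numbers: the SRE classifier recovers essentially all planted
blasts (balanced accuracy 0.998 on annotated cells never used in training),
while the one-dimensional CD45low gate reaches only 0.625 — three of the four
planted aberration classes leave CD45 untouched, which is exactly the failure
mode of single-marker gating.  The LOPO validation accuracy is lower (0.739)
because with only four patients, each held-out patient's aberration class is
unseen during that fold.  Staging assigns 87 % of healthy cells their true
developmental stage, and patient P1's predicted blasts sit at the immature
end of the map, matching the stage its blasts were planted at.

A command-line interface mirrors the library
(`cytoblast simulate | preprocess | train | detect | annotate`); see
`cytoblast --help`.

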