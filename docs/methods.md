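# Methods

## Problem setting and model

Bone-marrow cells measured on a 23-channel spectral cytometry panel
(21 antibodies: CD45, CD19, CD3, CD4, CD8, CD56, CD34, CD45RA, HLA-DR,
CD117, CD38, CD33, CD35, CD13, CD123, CD64, CD11b, CD11c, CD14, CD203c,
CD71; plus FSC and SSC) are classified as healthy or blast by anomaly
detection.  The anomaly detector is an autoencoder trained exclusively on
remission (healthy reference) cells: an encoder compresses the scaled
23-channel vector to a 4-dimensional latent code, a mirrored decoder
reconstructs it, and the training loss is the mean squared reconstruction
error (the variational variant adds `kl_weight ×` KL divergence to a
standard normal prior).  Immunophenotypes absent from healthy development
reconstruct poorly; the per-marker squared reconstruction error (SRE) is the
feature vector of a supervised blast classifier.

Remission cells are assumed blast-free — clinically justified when
remission samples carry ≤0.02 % residual disease — and the remission pool is
split once into an autoencoder-training half and a remission-test half.  The
remission-test half is the classifier's healthy class, so the classifier
never sees cells the autoencoder trained on; annotated non-remission blasts
are its positive class.

## Preprocessing

Raw intensities are transformed per channel with `asinh(x / c)`.  Cofactors
default to 1,000 for antibody channels and 10,000 for scatter (the usual
order of magnitude for spectral panels, where per-marker tuning spans
roughly 500–10,000) and are per-channel configurable; scatter channels go
through the same transform with their larger cofactor rather than a separate
code path.  Min-max scaling is fitted on training data only and reused on
validation/test data; held-out values outside the training range are *not*
clipped — downstream models must tolerate values outside [0, 1], and
clipping would erase exactly the extreme values anomaly detection needs.  A
constant channel scales to 0 by convention (the division is otherwise
undefined).  Event ingestion reads FCS 3.0/3.1 (float32/float64 list mode)
or delimited tables and subsamples to a per-file cap (default 10,000 events)
with an RNG keyed by (seed, file name), so results do not depend on the
order files are processed.

## Autoencoder implementation and hyperparameter search

The networks are small fully-connected stacks (default encoder widths
23→16→8, latent 4) implemented directly on numpy with Glorot initialisation
and an Adam optimiser (lr 1e-3, batch 256, 30 epochs by default); at these
sizes a deep-learning framework buys nothing and the implementation is fully
deterministic under the config seed.  The VAE clips log-variances to ±10 for
numerical safety, and both its latent encoding and its reconstruction use
the posterior mean so SRE features are reproducible.  A non-finite loss
raises a divergence error naming the configuration.

The randomised search samples hyperparameter settings (encoder depth 1–3
hidden layers, widths 8–64 sorted decreasing, latent dimension 2–6,
activation relu/tanh, learning rate log-uniform 1e-4–1e-2) and trains every
setting as both plain and variational architecture on every fold of a
cell-level k-fold split (default 5), refitting the min-max scaler on each
fold's training part.  The (setting, architecture) pair with the lowest
fold-mean validation MSE is retrained on the full training set.  With 100
settings, both architectures and 5 folds this is exactly 1,000 fits; the
trainer is injectable so accounting can be verified with a stub.

## Blast classifier

Leave-one-patient-out balanced splits: the remission-test pool is
partitioned into one equal validation share per blast-contributing patient;
fold *i* validates on share *i* plus patient *i*'s blasts subsampled without
replacement to the share size, and trains on the remaining shares plus the
other patients' blasts subsampled to the remaining-share size.  A patient
with fewer blasts than the share contributes all of them and the fold is
flagged imbalanced rather than upsampled.  Model selection samples
(family, hyperparameters) pairs over SVM, logistic regression, small MLPs
and random forests, keeps the highest fold-mean validation accuracy, and
retrains on all remission-test cells plus an equal-size blast subsample.  No
family is hard-coded; the winner is recorded per run.  Scores threshold at
the family's native boundary (0.5 posterior / zero margin).

Baselines: the CD45low gate (cells below a CD45 threshold in arcsinh space,
defaulting to the panel's CD45 positivity threshold) and classifiers trained
directly on scaled expression, including an MLP with hidden widths (10, 4)
whose 4-unit layer activations are exposed for latent-space comparison.  The
expression baselines fit their own min-max scaler, never the autoencoder's.

## Latent staging, composition and surviving cells

The remission-test cells' latent coordinates with their stage labels form
the reference map; only remission cells are admitted as neighbors.  Queries
are staged by majority vote among the k = 5 nearest reference cells
(Euclidean distance); ties break to the label with the smaller summed
neighbor distance, then lexicographically, making assignment deterministic.
Per-sample composition vectors are stage fractions over predicted blasts
(a flag switches to all cells), compared across timepoints by Euclidean
distance.

The surviving-cell analysis fits one maximum-likelihood Gaussian (a
single-component mixture) to the diagnosis and one to the relapse latent
encoding, full covariance with 1e-6 added to the diagonal (small latent
dimensions make near-singular fits likely); a diagonal-covariance constraint
is available behind a flag.  A diagnosis cell is flagged
"diagnosis-like-relapse" iff its log-density under the relapse Gaussian
strictly exceeds that under the diagnosis Gaussian (exact equality resolves
to not flagged), and symmetrically for relapse cells.

## Clustering stability and annotation

The clustering backend is pluggable (`backend(X, k, seed) → labels`); a
k-means default ships so no external clustering package is required, while
self-organising-map or graph-community backends drop in unchanged.  For
each k the backend runs n_repeats times (default 10) with seeds derived
from (seed, k, repeat) — invariant to the order of k values — and each run
is scored by its mean adjusted Rand index against its sibling repeats of the
same k (a pooled mode averages across all runs instead); the most stable
run wins, ties breaking to lowest k then lowest repeat index.

Cluster annotation works on per-cluster arcsinh medians.  Debris is checked
first: a cluster below threshold on every lineage marker (CD45, CD34, CD33,
CD64, HLA-DR, CD71) is not a cell population, so the aberrancy criteria do
not apply to it.  Otherwise any satisfied blast criterion — (a) aberrant
CD56, (b) abnormally low CD33 or CD45, (c) asynchronous CD117
overexpression without CD34 but with CD4 — labels the cluster blast;
otherwise the cell-type signature with the highest fraction of satisfied
high/low expectations wins, ties breaking in maturation order.  All
thresholds live in configuration: the published workflow made these calls by
manual inspection, so the defaults here are tuned to the synthetic
trajectory and must be reviewed for real panels.

## Marker dynamics and individuality

Positivity is evaluated on arcsinh-transformed, *unscaled* values with
strict `>` at the marker threshold — thresholds are marker-native
quantities, while min-max scaling is model-specific.  Change accounting
takes matched per-patient diagnosis/relapse positivity rows; a marker is
gained (lost) for a patient when the fraction changes by strictly more than
+δ (−δ), δ = 0.05 by default, so a change of exactly 5 % counts as neither.

The individuality score for each cell counts its k nearest neighbors
(k = 15 default, Euclidean distance in scaled expression space, the query
excluded) per class, weights counts by inverse class size and normalises
across classes to a posterior summing to 1; the per-class mean own-posterior
measures how self-contained each class is.  A literal fixed-denominator
variant (divide by `Σ_j 1/n_class_j` without row normalisation) is available
behind `normalize=False`; its rows do not sum to 1, which is why the
normalised form is the default.

## Synthetic bone-marrow generator

The generator emulates the monocytic arm of myelopoiesis as a continuous
pseudotime axis t ~ Uniform(0, 1).  Every marker follows a monotone logistic
response curve in arcsinh space (low/high plateau, midpoint, width) — e.g.
CD34 and CD117 fall early, CD33 and CD13 rise mid-trajectory, CD64/CD11b/
CD11c rise late and CD14 rises last; lymphoid markers stay near baseline.
Stage labels come from cutpoints at t = 0.25 / 0.50 / 0.75, so stage
structure emerges from curve plateaus rather than discrete clusters,
matching the continuous trajectories seen in real bone marrow.  Gaussian
noise (SD 0.35 for antibodies, 0.15 for scatter) is added in arcsinh space,
where cytometry noise is approximately homoscedastic after variance
stabilisation; adjacent stage archetypes differ by at least ~3 noise SDs on
their defining markers.  Raw intensities are recovered as
`cofactor · sinh(value)` so the real preprocessing path is exercised
end-to-end.

Blasts are drawn at an anchor pseudotime (default 0.30, SD 0.05) with
aberration shifts planted at a stated penetrance (default 1.0).  The default
catalog carries one entry per aberrancy class: CD56 gain (+3.0), CD45 loss
(−2.5), CD33 loss (−2.8), and asynchronous CD117 +2.5 / CD34 −2.5 / CD4
+2.0 — magnitudes of 2–4 arcsinh units, the scale of real
leukemia-associated immunophenotypes.  Cohorts cycle patients through the
catalog with per-patient anchor jitter so patients are individual; blast
counts per sample are exact by construction, remission samples contain no
blasts, and regeneration from (config, seed) is bitwise identical.  An
optional relapse shift plants a minority diagnosis subclone (default 5 %)
drawn from the relapse anchor phenotype, giving the surviving-cell analysis
a known recovery target.

What the generator does *not* emulate: spectral spillover, batch and
acquisition-time effects, doublets and debris, patient-level biological
variation beyond the aberration catalog, or non-monocytic lineages.  Passing
tests therefore demonstrate correctness of the algorithms and recoverability
of planted structure under idealised noise — not clinical performance on
deposited cohorts, whose headline accuracies depend on manual annotation
quality and real biological heterogeneity.

## Problem sizes and numerical choices

Default test and acceptance runs use a cohort of 10 patients × 10,000
cells/sample plus 5 remission samples (250,000 cells), an autoencoder
training cap of 20,000 cells, a classifier pool of 6,000 remission-test
cells, and 4 classifier-selection trials over the fast families (logistic
regression, random forest) — sizes chosen so a full run completes in
minutes on one CPU while leaving per-fold classes in the thousands.  The
full model space (SVM, MLP) and 100-trial searches remain available through
function arguments.  Seeds propagate through `numpy.random.SeedSequence`
children keyed by purpose, so every stage is independently reproducible.

Known limitations: the LOPO validation accuracy is pessimistic when the
cohort has fewer patients than aberration classes (each held-out class is
then unseen); kNN staging degrades near stage cutpoints, which bounds stage
recovery below 100 % by construction; and the annotation rule thresholds are
synthetic-panel defaults, not clinical calibrations.
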