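# Methods

## Problem and model

`ccpredict` implements a small-cohort, two-class microarray classification
pipeline of the kind used to ask whether the transcriptome of follicular
somatic cells (cumulus or mural granulosa cells) predicts oocyte
competence — live birth (LB) versus no pregnancy (NP) in a training cohort,
blastocyst (B) versus poor-quality embryo (EP) in external validation
cohorts.  The statistical setting is hostile: order 10–15 samples per
class, tens of thousands of probes, large within-group variance and small
between-group fold changes, so every design choice below is about keeping
the error estimate honest at that scale.

The pipeline is:

1. **Pre-filters** (label-free, applied once up front):
   - keep only probes with functional annotation (protein-coding or
     non-coding);
   - keep probes whose arithmetic mean intensity across *all* samples is
     strictly greater than a background floor (default 10, unlogged
     intensity units).  "Strictly greater" is a deliberate reading of
     "average expression above" the floor; the boundary case (mean exactly
     at the floor) is removed.
   Neither filter sees the class labels, so applying them before
   cross-validation introduces no selection bias.
2. **Nested leave-one-out cross-validation (LOOCV).**  For each held-out
   sample, probes are selected by a two-sided two-sample t-test computed on
   the remaining samples only (`p < cutoff`, no multiple-testing
   correction — the aim is prediction, not discovery), the classifier is
   trained on those probes, and the held-out sample is predicted.  The
   selection cutoff is scanned over the grid {0.001, 0.005, 0.01, 0.05}
   crossed with three classifier families.
3. **Model choice**: maximal LOOCV accuracy; ties prefer fewer selected
   features (median across folds), then SVM over kNN over dLDA.
4. **Final signature**: probes passing the chosen cutoff on the *full*
   data set, annotated with their cross-validation support (the percentage
   of folds whose in-fold selection also chose them) and ordered by
   descending support then ascending p.
5. **Permutation significance**: the entire nested LOOCV (including
   in-fold selection) is re-run on label permutations (default 1000); the
   p-value is the plain proportion of permutations with error at or below
   the observed error (no +1 smoothing by default; a smoothed variant is
   available).
6. **ROC/AUC** of the LOOCV predictive probabilities (trapezoid).
7. **Cross-platform transfer**: signature genes are matched to a second
   platform by gene symbol; redundant target probes are resolved to the
   *intermediate-expression* probe (median rank by mean log2 expression
   over the validation samples; lower median on even counts).  A linear
   SVM is retrained on the source cohort restricted to the mapped genes and
   applied to the external cohort over a cost grid {1, 2, 10}.

## Classifier families

- **dLDA** — Gaussian discriminant with shared diagonal covariance:
  per-feature pooled within-class variances `s²_g`, equal class priors.
  Prediction minimizes `Σ_g (x_g − m_{c,g})² / s²_g`.  Probabilities are
  the Gaussian posterior (softmax of `−d_c/2`).  Pooled variances are
  floored at `1e-8 ×` their mean so constant (background) probes cannot
  produce infinities.
- **kNN** — Euclidean distance, odd `k` (1 or 3), probability = neighbour
  vote fraction.  Distance ties at the k-th rank keep the earlier-indexed
  training sample (stable sort), making predictions deterministic.
- **Linear soft-margin SVM** — the standard hinge-loss problem at cost
  `C`; solved by scikit-learn's `SVC(kernel="linear")` (the contract fixes
  the optimization problem, not the solver).  Probabilities come from
  logit (Platt-style) calibration: decision values from seeded 3-fold
  stratified inner refits, then a maximum-likelihood logistic map
  `p = 1/(1+exp(A·f+B))` with a small ridge (C=100) so perfectly separated
  decision values yield a finite slope; `A < 0` is enforced, so probability
  is strictly increasing in the decision value.

Everywhere the classification rule is `p(positive) > 0.5`; exactly 0.5
resolves to the negative class — never predict the positive outcome on
zero evidence.  A fold in which no probe passes selection predicts the
fold's training-majority class at `p = 0.5` and is logged rather than
aborting the run.

In the model-selection grid, LOOCV runs without calibration (SVM folds
predict by the sign of the decision value, as in standard SVM use); the
chosen configuration is then re-run with calibrated probabilities and that
run supplies the reported metrics, the signature support and the ROC
curve.  The two rules can disagree only when the Platt midpoint is
displaced from decision value zero, which with near-balanced classes is a
small effect.

## t-test details

Default is the pooled-variance (Student) two-sample t-test on the working
(unlogged) scale, two-sided; Welch is available behind
`FeatureSelectionConfig(test="welch")`.  A probe with zero within-class
variance in both classes gets `p = 1` (no variance, no t-evidence), even
if its class means differ.  Fold changes are reported signed: ratio of
positive-class to negative-class mean, with ratios below 1 written as the
negative reciprocal; on log2 matrices the ratio is `2^(mean difference)`.

Inside LOOCV, per-fold Student selection is computed from cached per-class
sums and sums of squares minus the held-out column, thresholded at the
critical t value.  This is algebraically identical to recomputing
per-probe p-values in each fold (a test asserts exact equivalence) and is
what makes 1000-permutation runs on ~15k probes take well under a minute.

## Cross-platform bridge

The two platforms report intensities on incomparable scales, and the
training-side SVM weights are meaningless on raw external intensities.
The bridge imposed here: each mapped gene is standardized to zero mean and
unit variance *within each data set independently* before training and
prediction.  This makes external prediction invariant to any affine
rescaling (positive slope) of the external platform and is this module's
largest modelling inference — it is a declared design choice of this
package, not a claim about how any particular published analysis bridged
platforms.  External samples are never used to refit anything; only the
SVM cost is swept.

Signature probes without a gene symbol cannot cross platforms and are
skipped; "unique genes" means unique non-empty symbols in signature order.

## Synthetic data generator

The generator is the test bed for the whole pipeline and defines the study
conditions everything is validated under:

| parameter | default | meaning |
|---|---|---|
| `n_pos` / `n_neg` | 12 / 15 | class sizes of the training cohort |
| `n_probes` | 20,000 | probes on the training platform |
| `frac_unannotated` | 0.15 | probes without functional annotation |
| `frac_background` | 0.10 | probes with mean below the floor |
| `background_threshold` | 10 | intensity floor (unlogged) |
| `n_de` | 30 | planted differentially expressed probes |
| `fold_change` | 4 | multiplicative class effect (half up, half down) |
| `cv_within` | 0.3 | within-group coefficient of variation |
| `baseline_log_mean/sd` | 5 / 1.2 | log-normal baseline above the floor (natural log) |
| `frac_noncoding` | 0.25 | non-coding share among annotated probes |
| `probes_per_gene_target` | (1,2,3) | redundant probes per gene, 2nd platform |
| `frac_genes_missing_target` | 1/6 | genes absent from the 2nd platform |

Baseline intensities are log-normal shifted above the floor; background
probes draw means uniformly below it.  Noise is multiplicative log-normal
with unit mean at the configured CV — the standard intensity noise model
for arrays.  Planted probes are always annotated and never background,
with balanced up/down directions.  The external platform redraws a fresh
cohort from the same class-effect model (endpoint names B/EP), gives each
kept gene 1–3 probes with log-normal affinities, emits intensities on a
0.25× global scale and log2-transforms them.  All randomness flows from
the config seed; the external generator uses the independent stream
`[seed, 104729]`, and permutation `b` of the significance test uses
`[seed, b]`, so every component is independently reproducible.

What the generator does **not** emulate: batch and dye effects, probe
sequence-specific cross-hybridization, correlated gene modules, heavy-tailed
outlier samples, and class-imbalanced label noise.  Passing tests on this
generator therefore demonstrate that the *machinery* is correct and
leakage-free, not that any particular biological cohort is classifiable.

## Problem sizes used in tests and the acceptance script

Routine tests run on 150–2,000-probe simulations; the leakage check uses
ten replicate 27-sample, 2,000-probe null cohorts; permutation-calibration
checks use 50 replicates at 300 probes with 200 permutations; the
parameter-recovery check and the acceptance script use the full default
20,000-probe configuration with 1000 permutations.  These sizes are chosen
so the complete suite and the script each finish in a few minutes on one
CPU while keeping every statistical check at its intended power.

A note on the leakage check: a *single* null LOOCV run has strongly
correlated fold outcomes plus the well-known slight pessimistic bias of
cross-validating with in-fold selection on null data, so its accuracy
scatters far wider than a binomial draw (empirically sd ≈ 0.15 at n = 27).
The chance-level assertion is therefore made on the mean over ten
replicate null cohorts, while the leaky variant (selection once on all
samples before LOOCV) must exceed 0.7 — the contrast between the two is
the leakage-control property.

## Numerical and degenerate-input choices

- Matrices must be complete; an empty or non-numeric cell is a parse error
  with coordinates, not a missing value.
- TSV round trips are exact: floats are serialized at shortest round-trip
  precision and parsed with a correctly rounded parser.
- Undefined confusion ratios (zero denominators) are reported as 0.0 and
  flagged in `Metrics.undefined`, matching the convention of printing 0
  for a classifier that never predicts a class.
- `choose_optimal` and all tie-breaks are deterministic and documented
  (accuracy, then median selected features, then SVM > kNN > dLDA).
- Permutation p-values are unsmoothed proportions by default; with 1000
  permutations the smallest attainable value is 0.

## Known limitations

- LOOCV only; no k-fold or repeated schemes.
- Two classes only; no multiclass, no nonlinear kernels.
- The cross-platform z-score bridge assumes the external cohort is large
  and mixed enough for per-gene standardization to be meaningful; tiny or
  single-class external sets would distort it.
- The final signature is selected on the full data set (its error was
  estimated by the nested CV of the same rule); union/intersection of
  fold selections are not offered.
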