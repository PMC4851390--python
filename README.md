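# ccpredict

Oocyte-competence classification from follicular-cell expression profiles.

IVF laboratories would like a non-invasive marker of which embryo to
transfer.  One candidate readout is the transcriptome of the somatic cells
surrounding the oocyte — cumulus cells (CC) and mural granulosa cells
(MGC) — profiled by expression microarray and classified against a
competence endpoint: live birth (LB) vs no pregnancy (NP), or blastocyst
(B) vs poor-quality embryo (EP).  Cohorts in this setting are tiny (order
10–15 samples per class against ~20,000 probes), so the analysis lives or
dies by leakage control: any feature selection performed outside the
cross-validation loop silently inflates accuracy far above chance.

`ccpredict` is a tested implementation of that analysis:

- **nested leave-one-out cross-validation** with univariate t-test feature
  selection performed *inside every fold* (`p < cutoff`, grid
  {0.001, 0.005, 0.01, 0.05});
- three classifier families — **diagonal linear discriminant analysis**
  (dLDA), **k-nearest neighbours** (1-NN/3-NN), and the **linear
  soft-margin SVM** — with logit (Platt-style) probability calibration and
  the decision rule `p(positive) > 0.5`;
- **permutation significance** of the cross-validated error rate (the full
  nested pipeline re-run on, by default, 1000 label permutations);
- **ROC/AUC** of the cross-validated predictive probabilities;
- **cross-platform signature transfer**: gene-symbol mapping to a second
  array platform, redundant probes resolved to the intermediate-expression
  probe, per-gene z-score bridging, external validation over an SVM cost
  grid {1, 2, 10};
- a **synthetic-data generator** that reproduces the statistical structure
  of such studies (log-normal baselines, below-background probes,
  unannotated probes, planted fold changes, a redundant-probe second
  platform), so the whole pipeline runs and is validated without any
  external download.

For a fold with selected probe set G, the dLDA discriminant is
`d_c(x) = Σ_{g∈G} (x_g − m_{c,g})² / s²_g` with pooled per-gene variances
`s²_g`; the SVM decision value is `f(x) = w·x + b` and its calibrated
probability `p(LB|x) = 1 / (1 + exp(A·f(x) + B))`, `A < 0`.  The
permutation p-value is `#{error_perm ≤ error_obs} / n_perm`, and AUC is
the trapezoidal area under the TPR-vs-FPR sweep (equal to the
Mann–Whitney pair-winning fraction).

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small study (2,000 probes, 12 LB vs 15 NP, 30 planted probes at
fold change 4) and run the full pipeline:

```
ccpredict simulate --out-dir demo --n-probes 2000 --seed 7
ccpredict run-all \
    --matrix demo/matrix.tsv --annotation demo/annotation.tsv \
    --labels demo/labels.tsv \
    --external-matrix demo/external_matrix.tsv \
    --external-annotation demo/external_annotation.tsv \
    --external-labels demo/external_labels.tsv \
    --n-perm 200 --seed 0 --out-dir demo/results
```

prints (abridged):

```
"chosen": {
 "model": "SVM linear, cost 1",
 "p_cutoff": 0.001,
 "accuracy": 1.0,
 "metrics": {"tp": 12, "fn": 0, "tn": 15, "fp": 0, ...}
},
"roc": {"auc": 1.0},
"permutation": {"observed_error": 0.0, "p_value": 0.005, "n_perm": 200, ...}
```

Reading this: of the 2,000 simulated probes, 1,700 carry annotation and
1,524 pass the background filter (`report.json`, `filtering`).  The
model-selection grid (3 algorithms × 4 cutoffs; `model_grid.tsv`) is won
by the linear SVM at the tightest cutoff, which classifies all 27 samples
correctly under nested LOOCV — the planted fold-change-4 signal is strong.
Exactly one of the 200 label permutations matched its zero error rate
(p = 1/200 = 0.005), and the AUC of the cross-validated probabilities
is 1.0.  The final
signature (`signature.tsv`) lists 31 probes, every one selected in 100% of
the cross-validation folds:

```
probe_id  gene_symbol  p_value                 cv_support
P01459    GENE01244    5.530022106461844e-13   100.0
P00034    GENE00029    7.630377098242826e-12   100.0
...
```

26 of its 31 genes exist on the simulated second platform; the transferred
signature classifies the external B/EP cohort perfectly at every cost
(`external_probabilities.tsv`, `report.json`).

On *null* data (`--fold-change 1`) the same pipeline stays at chance-level
accuracy and its permutation p-values are uniform — that, not the perfect
score above, is the hard part, and it is what the test suite asserts.

Every stage is also available as its own subcommand (`filter`, `train-cv`,
`permute`, `roc`, `translate`, `validate-external`), and chaining them
manually reproduces the orchestrated run exactly.  The same functionality
is importable as a library (`ccpredict.loocv`, `ccpredict.run_study`, ...).

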