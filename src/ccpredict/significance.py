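"""Permutation significance of the cross-validated error rate, and ROC/AUC.

The permutation test asks whether the LOOCV misclassification rate could
plausibly arise by chance: the class labels are randomly permuted (class
sizes preserved) and the *entire* nested cross-validation — including the
in-fold feature selection — is repeated for each permutation.  The p-value
is the proportion of permutations whose error rate is at or below the
observed one.  No +1 smoothing is applied by default, matching the plain
"proportion of permutations" definition; a smoothed variant is available.

ROC evaluation sweeps a threshold over the predictive probabilities and
reports the trapezoidal area under the TPR-vs-FPR curve, where AUC 0.5 is
random ranking and 1.0 perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

from .classifiers import ClassifierSpec, ConfigurationError
from .expression_io import DomainError, ExpressionMatrix, LabelVector
from .nested_cv import loocv


@dataclass
class PermutationResult:
    observed_error: float
    null_errors: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed_error": self.observed_error,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_error_mean": float(np.mean(self.null_errors)),
        }


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending score cutoffs
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _permuted_labels(y: LabelVector, sample_ids, rng) -> LabelVector:
    perm = rng.permutation(len(sample_ids))
    labels = {s: y.labels[sample_ids[j]] for s, j in zip(sample_ids, perm)}
    return LabelVector(labels, y.positive_name, y.negative_name)


def permutation_test(X: ExpressionMatrix, y: LabelVector, spec: ClassifierSpec,
                     n_perm: int = 1000, seed: int = 0,
                     smoothed: bool = False, test: str = "student") -> PermutationResult:
    """Permutation p-value of the LOOCV misclassification rate.

    Each of the ``n_perm`` permutations re-runs the full nested LOOCV
    (selection inside every fold) on a uniformly permuted label vector.
    Permutation ``b`` uses the seed pair ``(seed, b)``, so individual
    permutations are reproducible independently; class sizes are preserved
    by construction.  ``p_value = #(null error <= observed error) / n_perm``
    (or ``(count+1)/(n_perm+1)`` if ``smoothed``).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    observed = 1.0 - loocv(X, y, spec, seed=seed, compute_proba=False,
                           test=test).accuracy
    sample_ids = X.sample_ids
    null_errors = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng([seed, b])
        y_perm = _permuted_labels(y, sample_ids, rng)
        cv = loocv(X, y_perm, spec, seed=seed, compute_proba=False, test=test)
        null_errors[b] = 1.0 - cv.accuracy
    count = int((null_errors <= observed).sum())
    p = (count + 1) / (n_perm + 1) if smoothed else count / n_perm
    return PermutationResult(observed, null_errors, p, n_perm, seed)


def roc_curve(scores, y: LabelVector, sample_ids=None) -> ROCResult:
    """ROC curve and trapezoidal AUC of predictive probabilities.

    ``scores`` is the per-sample probability of the positive class, aligned
    to ``sample_ids`` (default: label order).  Tied scores share one
    threshold; the curve starts at (0, 0) and ends at (1, 1).
    """
    if sample_ids is None:
        sample_ids = list(y.labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(sample_ids):
        raise DomainError("scores and sample ids are misaligned")
    truth = y.y(sample_ids)
    if truth.all() or (~truth).all():
        raise DomainError("ROC requires both classes present")
    fpr, tpr, thresholds = skmetrics.roc_curve(truth.astype(int), scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
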