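"""Leave-one-out cross-validation with in-fold feature selection.

This is the engine of the pipeline.  For every sample, the sample is set
aside, univariate two-sample t-tests are computed on the *remaining*
samples, probes passing the fold's p-value cutoff are selected, the
classifier is trained on those probes, and the held-out sample is predicted.
Selection therefore never sees the held-out sample — the leakage-control
property that distinguishes an honest error estimate from a biased one.

Model selection scans a grid of p-value cutoffs (default 0.001, 0.005,
0.01, 0.05) crossed with the classifier families, and picks the entry with
the best LOOCV accuracy, breaking ties toward smaller signatures.  The
per-probe *cross-validation support* — the percentage of folds in which a
probe passed selection — quantifies the stability of each signature member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import classifiers as clf
from .expression_io import (
    SCALE_LOG2,
    DomainError,
    ExpressionMatrix,
    LabelVector,
    Signature,
)

logger = logging.getLogger(__name__)

DEFAULT_P_GRID = (0.001, 0.005, 0.01, 0.05)


@dataclass
class FeatureSelectionConfig:
    """Grid of univariate-selection cutoffs and the t-test variant.

    ``test`` is ``"student"`` (pooled-variance two-sample t) or ``"welch"``.
    """

    p_grid: tuple = DEFAULT_P_GRID
    test: str = "student"

    def __post_init__(self):
        grid = tuple(float(p) for p in self.p_grid)
        if not grid or any(not 0 < p < 1 for p in grid):
            raise DomainError("all cutoffs must lie in (0, 1)")
        if list(grid) != sorted(set(grid)):
            raise DomainError("p_grid must be strictly increasing")
        if self.test not in ("student", "welch"):
            raise DomainError("test must be 'student' or 'welch'")
        self.p_grid = grid


@dataclass
class Metrics:
    """Confusion counts and the ratios derived from them.

    Ratios with a zero denominator are reported as 0.0 and their names
    recorded in ``undefined``.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "undefined": list(self.undefined),
        }


@dataclass
class FoldResult:
    held_out: str
    selected: list
    predicted: str
    proba: float
    true_label: str


@dataclass
class CVResult:
    """Outcome of one LOOCV run: per-fold records plus aggregate metrics."""

    per_fold: list
    accuracy: float
    per_class_accuracy: dict
    metrics: Metrics
    support: dict  # probe_id -> percent of folds selected (only probes > 0)
    n_selected_per_fold: list

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    @property
    def median_n_selected(self) -> float:
        return float(np.median(self.n_selected_per_fold))

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.held_out, f.true_label, f.predicted, f.proba, len(f.selected))
             for f in self.per_fold],
            columns=["sample_id", "true_label", "predicted", "p_positive",
                     "n_selected"],
        )


# ---------------------------------------------------------------------------
# univariate t statistics (vectorized over probes)


def _two_sample_t(values: np.ndarray, ypos: np.ndarray, test: str = "student"):
    """Per-probe two-sample t and two-sided p for probes-by-samples ``values``.

    Probes with zero variance in both classes cannot discriminate by t and
    get t = 0, p = 1.
    """
    a = values[:, ypos]
    b = values[:, ~ypos]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise DomainError("t-test requires at least 2 samples per class")
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "student":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full(values.shape[0], float(n1 + n2 - 2))
        else:  # welch
            se = np.sqrt(v1 / n1 + v2 / n2)
            num = (v1 / n1 + v2 / n2) ** 2
            den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            df = np.where(den > 0, num / den, 1.0)
        t = (m1 - m2) / se
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p, m1, m2


def _fold_change(m_pos: np.ndarray, m_neg: np.ndarray, scale: str) -> np.ndarray:
    """Signed fold change, positive over negative class, on the unlogged scale.

    Ratios below 1 are reported as the negative reciprocal (-1/ratio), the
    usual signed convention for down-regulated probes.  For log2 matrices
    the ratio is 2**(mean difference).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == SCALE_LOG2:
            ratio = np.exp2(m_pos - m_neg)
        else:
            ratio = np.where(m_neg > 0, m_pos / np.where(m_neg > 0, m_neg, 1.0),
                             np.inf)
            ratio = np.where((m_neg == 0) & (m_pos == 0), 1.0, ratio)
        fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return fc


def select_features_ttest(X: ExpressionMatrix, y: LabelVector, p_cutoff: float,
                          test: str = "student") -> Signature:
    """Probes with two-sided univariate-t p-value strictly below ``p_cutoff``.

    Returns a :class:`Signature` (cv_support filled with 0; attach support
    with :func:`final_signature`) ordered by ascending p-value.
    """
    if not 0 < p_cutoff < 1:
        raise DomainError("p_cutoff must lie in (0, 1)")
    ypos = y.y(X.sample_ids)
    t, p, m_pos, m_neg = _two_sample_t(X.values, ypos, test)
    fc = _fold_change(m_pos, m_neg, X.scale)
    keep = np.flatnonzero(p < p_cutoff)
    keep = keep[np.argsort(p[keep], kind="stable")]
    probe_ids = np.asarray(X.probe_ids, dtype=object)
    table = pd.DataFrame({
        "probe_id": probe_ids[keep],
        "gene_symbol": "",
        "t_statistic": t[keep],
        "p_value": p[keep],
        "fold_change": fc[keep],
        "cv_support": 0.0,
    })
    return Signature(table)


# ---------------------------------------------------------------------------
# LOOCV


def _fit_predict_fold(spec, Xtr, ytr, xq, seed, compute_proba):
    """Train one fold's classifier and predict the held-out sample."""
    if spec.algorithm == "dLDA":
        model = clf.train_dlda(Xtr, ytr, spec)
    elif spec.algorithm == "kNN":
        model = clf.train_knn(Xtr, ytr, spec)
    else:
        model = clf.train_linear_svm(Xtr, ytr, spec)
        if compute_proba:
            model = clf.calibrate_logit(model, Xtr, ytr, seed=seed)
    if compute_proba or spec.algorithm != "SVM_linear":
        proba = clf.predict_proba(model, xq)
        pred = proba > 0.5
    else:
        proba = None
        pred = clf.svm_decision_value(model, xq) > 0
    return bool(pred), proba


def _fold_selection_student(V, ypos, i, t_crit, cache):
    """Selection mask for the fold holding out sample ``i`` (pooled t).

    Uses per-class sums minus the held-out column, and compares |t| against
    the precomputed critical value — algebraically identical to computing
    per-probe p-values on the training samples and thresholding at
    ``p < p_cutoff``, but O(probes) per fold.
    """
    S1, Q1, S2, Q2, n_pos, n_neg = cache
    v = V[:, i]
    if ypos[i]:
        s1, q1, n1 = S1 - v, Q1 - v * v, n_pos - 1
        s2, q2, n2 = S2, Q2, n_neg
    else:
        s1, q1, n1 = S1, Q1, n_pos
        s2, q2, n2 = S2 - v, Q2 - v * v, n_neg - 1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = np.maximum(q1 - n1 * m1 * m1, 0.0)
    ss2 = np.maximum(q2 - n2 * m2 * m2, 0.0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    # se == 0 means no within-class variance: t is undefined, p := 1
    return (np.abs(m1 - m2) > t_crit * se) & (se > 0)


def loocv(X: ExpressionMatrix, y: LabelVector, spec: clf.ClassifierSpec,
          seed: int = 0, compute_proba: bool = True,
          test: str = "student") -> CVResult:
    """Leave-one-out cross-validation with selection inside every fold.

    For each sample: hold it out, run the univariate t-test on the remaining
    samples only, keep probes with p < ``spec.p_cutoff``, train ``spec``'s
    classifier on the remaining samples restricted to those probes, and
    predict the held-out sample.  A fold selecting zero probes predicts the
    fold's training-majority class at p = 0.5 (and is logged).

    ``seed`` affects only classifier-internal randomness (the calibration
    splits); folds are processed in input sample order.
    """
    sample_ids = X.sample_ids
    n = len(sample_ids)
    ypos = y.y(sample_ids)
    if ypos.sum() < 3 or (~ypos).sum() < 3:
        raise DomainError("LOOCV requires at least 3 samples per class")
    V = X.values
    probe_ids = np.asarray(X.probe_ids, dtype=object)
    sel_counts = np.zeros(V.shape[0], dtype=np.int64)
    per_fold = []
    n_selected = []
    correct_pos = correct_neg = 0
    if test == "student":
        pos = V[:, ypos]
        neg = V[:, ~ypos]
        cache = (
            pos.sum(axis=1), (pos * pos).sum(axis=1),
            neg.sum(axis=1), (neg * neg).sum(axis=1),
            int(ypos.sum()), int((~ypos).sum()),
        )
        t_crit = stats.t.isf(spec.p_cutoff / 2.0, n - 3)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if test == "student":
            sel = _fold_selection_student(V, ypos, i, t_crit, cache)
        else:
            _, p, _, _ = _two_sample_t(V[:, tr], ypos[tr], test)
            sel = p < spec.p_cutoff
        n_sel = int(sel.sum())
        if n_sel == 0:
            n_pos_tr = int(ypos[tr].sum())
            n_neg_tr = int((~ypos[tr]).sum())
            pred = n_pos_tr > n_neg_tr  # tie -> negative
            proba = 0.5
            logger.warning(
                "fold %d (%s): no probes passed p < %g; predicting the "
                "training-majority class", i, sample_ids[i], spec.p_cutoff,
            )
        else:
            Xtr = V[np.ix_(sel, tr)].T
            xq = V[sel, i]
            pred, proba = _fit_predict_fold(
                spec, Xtr, ypos[tr], xq, seed + i, compute_proba)
            sel_counts[sel] += 1
        truth = ypos[i]
        if pred == truth:
            if truth:
                correct_pos += 1
            else:
                correct_neg += 1
        per_fold.append(FoldResult(
            held_out=sample_ids[i],
            selected=list(probe_ids[sel]) if n_sel else [],
            predicted=y.positive_name if pred else y.negative_name,
            proba=proba,
            true_label=y.labels[sample_ids[i]],
        ))
        n_selected.append(n_sel)
    n_pos = int(ypos.sum())
    n_neg = n - n_pos
    tp, fn = correct_pos, n_pos - correct_pos
    tn, fp = correct_neg, n_neg - correct_neg
    metrics = confusion_metrics(tp, fn, tn, fp)
    nonzero = np.flatnonzero(sel_counts)
    support = {probe_ids[j]: 100.0 * sel_counts[j] / n for j in nonzero}
    return CVResult(
        per_fold=per_fold,
        accuracy=(tp + tn) / n,
        per_class_accuracy={
            y.positive_name: tp / n_pos,
            y.negative_name: tn / n_neg,
        },
        metrics=metrics,
        support=support,
        n_selected_per_fold=n_selected,
    )


def loocv_grid(X: ExpressionMatrix, y: LabelVector, specs,
               seed: int = 0, compute_proba: bool = False,
               test: str = "student") -> list:
    """Run LOOCV for every spec; returns [(spec, CVResult), ...]."""
    return [(s, loocv(X, y, s, seed=seed, compute_proba=compute_proba,
                      test=test)) for s in specs]


_ALGO_PREFERENCE = {"SVM_linear": 0, "kNN": 1, "dLDA": 2}


def choose_optimal(results) -> tuple:
    """Best (spec, CVResult) by accuracy; ties prefer smaller signatures.

    Tie order: higher accuracy, then fewer selected features (median across
    folds), then algorithm preference SVM > kNN > dLDA.
    """
    results = list(results)
    if not results:
        raise DomainError("choose_optimal requires a non-empty result list")

    def key(entry):
        spec, cv = entry
        return (-cv.accuracy, cv.median_n_selected, _ALGO_PREFERENCE[spec.algorithm])

    return min(results, key=key)


def final_signature(X: ExpressionMatrix, y: LabelVector, p_cutoff: float,
                    cv: CVResult, annot=None, test: str = "student") -> Signature:
    """Signature from full-data selection at ``p_cutoff`` with CV support.

    Probes are selected on the complete data set (the model-building rule
    the cross-validation estimated the error of), each annotated with the
    percentage of LOOCV folds that also selected it, and ordered by
    descending support then ascending p-value.  ``annot`` optionally fills
    in gene symbols.
    """
    sig = select_features_ttest(X, y, p_cutoff, test)
    if len(sig) == 0:
        raise DomainError(
            f"no probes pass p < {p_cutoff}; consider a larger cutoff"
        )
    table = sig.table.copy()
    table["cv_support"] = [cv.support.get(p, 0.0) for p in table["probe_id"]]
    if annot is not None:
        table["gene_symbol"] = [
            annot.symbol(p) if p in annot else "" for p in table["probe_id"]
        ]
    table = table.sort_values(
        ["cv_support", "p_value"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return Signature(table)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> Metrics:
    """Accuracy, sensitivity, specificity, PPV and NPV from the four counts.

    A ratio with zero denominator is reported as 0.0 and flagged in
    ``Metrics.undefined`` (this mirrors reporting 0 for a classifier that
    never predicts a class).
    """
    counts = (tp, fn, tn, fp)
    if any(c < 0 for c in counts):
        raise DomainError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise DomainError("confusion counts are all zero")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    return Metrics(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=(tp + tn) / total,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )
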