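"""Classifier families used in model selection, plus probability calibration.

Three families are supported, matching the candidates evaluated during
cross-validated model selection:

* diagonal linear discriminant analysis (dLDA) — Gaussian discriminant with
  a shared diagonal covariance (per-feature pooled within-class variances)
  and equal class priors;
* k-nearest neighbours with Euclidean distance and odd ``k`` (1 or 3);
* soft-margin linear support vector machine at a configurable cost.

SVM decision values carry no probability scale of their own, so an SVM is
turned into a probabilistic classifier by logit (Platt-style) calibration:
a logistic map ``p(positive | x) = 1 / (1 + exp(A f(x) + B))`` with ``A < 0``
fitted by maximum likelihood to decision values obtained from seeded inner
cross-validated refits.  dLDA and kNN have native probability outputs
(Gaussian posterior and neighbour vote fraction, respectively).

The classification rule everywhere is ``p(positive) > 0.5``; a probability of
exactly 0.5 is resolved to the negative class (never predict the positive
outcome on zero evidence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .expression_io import DomainError

ALGORITHMS = ("dLDA", "kNN", "SVM_linear")

# pooled-variance floor, relative to the mean pooled variance across features;
# guards constant (background) probes without perturbing informative ones
_DLDA_VAR_FLOOR_REL = 1e-8


class ConfigurationError(ValueError):
    pass


class NotCalibratedError(RuntimeError):
    pass


@dataclass
class ClassifierSpec:
    """Algorithm family plus its hyperparameters and the selection cutoff.

    ``k`` applies to kNN only (positive odd integer); ``cost`` to the linear
    SVM only (positive real); ``p_cutoff`` is the univariate-t selection
    threshold used inside each cross-validation fold.
    """

    algorithm: str
    p_cutoff: float = 0.01
    k: int = None
    cost: float = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if not 0 < self.p_cutoff < 1:
            raise ConfigurationError("p_cutoff must lie in (0, 1)")
        if self.algorithm == "kNN":
            if self.k is None or self.k < 1 or self.k % 2 == 0:
                raise ConfigurationError("kNN requires a positive odd k")
        elif self.k is not None:
            raise ConfigurationError("k is only valid for kNN")
        if self.algorithm == "SVM_linear":
            if self.cost is None or self.cost <= 0:
                raise ConfigurationError("SVM_linear requires a positive cost")
        elif self.cost is not None:
            raise ConfigurationError("cost is only valid for SVM_linear")

    def label(self) -> str:
        if self.algorithm == "kNN":
            return f"{self.k}-NN"
        if self.algorithm == "SVM_linear":
            return f"SVM linear, cost {self.cost:g}"
        return "dLDA"


@dataclass
class TrainedModel:
    """A fitted classifier bound to an ordered feature list.

    ``params`` is family-specific: dLDA stores class means and pooled
    variances; kNN stores the training matrix and labels; the SVM stores its
    weight vector and bias.  ``calibration`` is the optional ``(A, B)`` pair
    of the logit map from SVM decision value to probability.
    """

    spec: ClassifierSpec
    feature_ids: list
    params: dict
    calibration: tuple = None

    def _check_query(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != len(self.feature_ids):
            raise DomainError(
                f"query has {x.shape[0]} features; model requires "
                f"{len(self.feature_ids)}"
            )
        return x

    # -- persistence (versioned text format) --------------------------------

    def to_json(self) -> str:
        def enc(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        doc = {
            "format_version": 1,
            "spec": {
                "algorithm": self.spec.algorithm,
                "p_cutoff": self.spec.p_cutoff,
                "k": self.spec.k,
                "cost": self.spec.cost,
            },
            "feature_ids": list(self.feature_ids),
            "params": {k: enc(v) for k, v in self.params.items()},
            "calibration": list(self.calibration) if self.calibration else None,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        if doc.get("format_version") != 1:
            raise ConfigurationError("unsupported model format version")
        spec = ClassifierSpec(**doc["spec"])
        params = {}
        for k, v in doc["params"].items():
            params[k] = np.asarray(v, dtype=float) if isinstance(v, list) else v
        cal = doc["calibration"]
        return cls(spec, doc["feature_ids"], params,
                   tuple(cal) if cal is not None else None)


# ---------------------------------------------------------------------------
# dLDA


def train_dlda(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
               feature_ids=None) -> TrainedModel:
    """Fit diagonal LDA on samples-by-features ``X`` with boolean labels ``y``.

    Stores per-class per-feature means and per-feature pooled within-class
    variances.  Prediction assigns the class minimizing
    ``sum_g (x_g - m_{c,g})^2 / s2_g`` (equal priors); ties go to the
    negative class.  Pooled variances are floored at a tiny fraction of
    their mean to tolerate constant features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DomainError("dLDA requires at least 2 samples per class")
    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    ss = ((X[y] - mu_pos) ** 2).sum(axis=0) + ((X[~y] - mu_neg) ** 2).sum(axis=0)
    s2 = ss / (X.shape[0] - 2)
    mean_s2 = s2.mean()
    floor = _DLDA_VAR_FLOOR_REL * (mean_s2 if mean_s2 > 0 else 1.0)
    s2 = np.maximum(s2, max(floor, np.finfo(float).tiny))
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[1]))
    return TrainedModel(spec, ids, {"mu_pos": mu_pos, "mu_neg": mu_neg, "s2": s2})


def _dlda_discriminants(model: TrainedModel, x: np.ndarray) -> tuple:
    p = model.params
    d_pos = (((x - p["mu_pos"]) ** 2) / p["s2"]).sum()
    d_neg = (((x - p["mu_neg"]) ** 2) / p["s2"]).sum()
    return d_pos, d_neg


# ---------------------------------------------------------------------------
# kNN


def predict_knn(train_X: np.ndarray, train_y: np.ndarray, query: np.ndarray,
                k: int) -> bool:
    """Majority class among the k Euclidean-nearest training samples.

    ``k`` must be odd, so the two-class majority is always defined.  Distance
    ties at the k-th rank keep the earlier-indexed training sample (stable
    sort), making the prediction deterministic.
    """
    frac = knn_vote_fraction(train_X, train_y, query, k)
    return frac > 0.5


def knn_vote_fraction(train_X: np.ndarray, train_y: np.ndarray,
                      query: np.ndarray, k: int) -> float:
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=bool)
    query = np.asarray(query, dtype=float).ravel()
    if k % 2 == 0 or k < 1:
        raise ConfigurationError("k must be a positive odd integer")
    if k > train_X.shape[0]:
        raise DomainError(f"k={k} exceeds {train_X.shape[0]} training samples")
    d2 = ((train_X - query) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")[:k]
    return float(train_y[order].mean())


def train_knn(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
              feature_ids=None) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[1]))
    return TrainedModel(spec, ids, {"train_X": X, "train_y": y.astype(float)})


# ---------------------------------------------------------------------------
# linear SVM


def train_linear_svm(X: np.ndarray, y: np.ndarray, spec_or_cost,
                     feature_ids=None) -> TrainedModel:
    """Fit a soft-margin linear SVM; stores the weight vector and bias.

    ``spec_or_cost`` may be a :class:`ClassifierSpec` or a bare cost.  The
    positive class is mapped to +1, so ``f(x) = w.x + b > 0`` predicts
    positive.
    """
    if isinstance(spec_or_cost, ClassifierSpec):
        spec = spec_or_cost
    else:
        spec = ClassifierSpec("SVM_linear", cost=float(spec_or_cost))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or (~y).all():
        raise DomainError("SVM training requires both classes")
    if np.allclose(X, X[0]):
        raise DomainError("all training samples identical; SVM is degenerate")
    clf = SVC(kernel="linear", C=spec.cost)
    clf.fit(X, y.astype(int))
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[1]))
    return TrainedModel(spec, ids, {"w": w, "b": b})


def svm_decision_value(model: TrainedModel, x: np.ndarray) -> float:
    x = model._check_query(x)
    return float(model.params["w"] @ x + model.params["b"])


# ---------------------------------------------------------------------------
# logit (Platt-style) calibration

# small ridge on the logistic fit guards against infinite slope when the
# inner-CV decision values are perfectly separated
_CALIBRATION_C = 100.0


def _fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple:
    f = np.asarray(decision_values, dtype=float).reshape(-1, 1)
    lr = LogisticRegression(C=_CALIBRATION_C)
    lr.fit(f, np.asarray(y, dtype=int))
    w = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    if not lr.classes_[1] == 1:  # pragma: no cover - sklearn orders 0,1
        w, b = -w, -b
    # p = sigmoid(w f + b) = 1/(1+exp(A f + B)) with A = -w, B = -b
    A, B = -w, -b
    if A >= 0:
        # anti-monotone fit can only arise from a worse-than-random model;
        # force an (essentially flat) increasing map to keep the contract
        A = -1e-6
    return A, B


def calibrate_logit(model: TrainedModel, X: np.ndarray, y: np.ndarray,
                    inner_folds: int = 3, seed: int = 0) -> TrainedModel:
    """Attach a logit probability map to a trained linear SVM.

    Decision values are produced by ``inner_folds``-fold stratified
    cross-validated refits on the training data (seeded), so the values the
    logistic map is fitted to are out-of-fold, as in Platt's procedure.
    Returns the same model object with ``calibration = (A, B)``.
    """
    if model.spec.algorithm != "SVM_linear":
        raise ConfigurationError("logit calibration applies to the linear SVM")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.sum() < 3 or (~y).sum() < 3:
        raise DomainError("calibration requires at least 3 samples per class")
    n_splits = min(inner_folds, int(y.sum()), int((~y).sum()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    f = np.empty(len(y))
    for tr, te in skf.split(X, y.astype(int)):
        sub = train_linear_svm(X[tr], y[tr], model.spec)
        f[te] = X[te] @ sub.params["w"] + sub.params["b"]
    model.calibration = _fit_platt(f, y)
    return model


# ---------------------------------------------------------------------------
# prediction interface


def predict_proba(model: TrainedModel, query: np.ndarray) -> float:
    """p(positive class | query) in [0, 1].

    dLDA: Gaussian posterior with equal priors (softmax of -discriminant/2);
    kNN: neighbour vote fraction; SVM: calibrated logit of the decision
    value (an uncalibrated SVM raises :class:`NotCalibratedError`).
    """
    x = model._check_query(query)
    alg = model.spec.algorithm
    if alg == "dLDA":
        d_pos, d_neg = _dlda_discriminants(model, x)
        m = min(d_pos, d_neg)
        e_pos = np.exp(-(d_pos - m) / 2.0)
        e_neg = np.exp(-(d_neg - m) / 2.0)
        return float(e_pos / (e_pos + e_neg))
    if alg == "kNN":
        return knn_vote_fraction(model.params["train_X"],
                                 model.params["train_y"].astype(bool),
                                 x, model.spec.k)
    if model.calibration is None:
        raise NotCalibratedError(
            "SVM probabilities require calibration; call calibrate_logit first"
        )
    A, B = model.calibration
    f = svm_decision_value(model, x)
    return float(1.0 / (1.0 + np.exp(A * f + B)))


def predict(model: TrainedModel, query: np.ndarray) -> bool:
    """Hard class call: True iff p(positive) > 0.5 (ties to negative).

    For an uncalibrated SVM the sign of the decision value is used directly
    (f(x) > 0 -> positive), which agrees with the calibrated rule because
    the logit map is strictly monotone.
    """
    x = model._check_query(query)
    if model.spec.algorithm == "SVM_linear" and model.calibration is None:
        return svm_decision_value(model, x) > 0
    return predict_proba(model, x) > 0.5


def train(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
          feature_ids=None) -> TrainedModel:
    """Dispatch to the family-specific trainer."""
    if spec.algorithm == "dLDA":
        return train_dlda(X, y, spec, feature_ids)
    if spec.algorithm == "kNN":
        return train_knn(X, y, spec, feature_ids)
    return train_linear_svm(X, y, spec, feature_ids)
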