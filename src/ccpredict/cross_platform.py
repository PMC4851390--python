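"""Cross-platform signature translation and external validation.

A signature trained on one array platform (probe ids specific to that
platform) is carried to a second platform through gene symbols.  Where the
target platform represents a gene by several redundant probes, the probe
with the *intermediate* expression value is used: candidates are ranked by
their mean (log2) expression across the validation samples and the
median-ranked probe is chosen (lower median for an even count).  Genes
absent from the target platform are dropped from the transferred signature.

Validation then trains a linear SVM on the original training samples
restricted to the signature genes and predicts the external samples.
Because the two platforms report intensities on incomparable scales, each
gene is standardized to zero mean and unit variance *within each data set
independently* before training/prediction — the bridge that makes the
trained weights portable.  The external samples are never used to refit the
model; only the SVM cost is swept over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers as clf
from .expression_io import (
    SCALE_LOG2,
    DomainError,
    ExpressionMatrix,
    LabelVector,
    ProbeAnnotation,
    Signature,
)
from .nested_cv import Metrics, confusion_metrics


@dataclass
class GeneResolution:
    gene: str
    candidates: list        # target probe ids carrying the symbol
    chosen: str
    candidate_means: dict   # probe -> mean expression over target samples


@dataclass
class MappedSignature:
    """Gene-level pairing of source probes to target probes.

    ``pairs`` maps one representative source probe per mapped gene (the
    signature's best-ranked probe for that gene) to the chosen target probe.
    ``unmapped_genes`` lists signature genes absent from the target platform,
    so ``len(pairs) + len(unmapped_genes)`` equals the number of unique genes
    in the source signature.  ``resolution_log`` records every redundant-probe
    decision for audit.
    """

    pairs: dict            # source probe id -> target probe id
    genes: dict            # gene symbol -> (source probe id, target probe id)
    unmapped_genes: list
    resolution_log: dict   # gene -> GeneResolution

    @property
    def n_mapped(self) -> int:
        return len(self.pairs)


def _intermediate_probe(candidates, means):
    """Median-ranked candidate by mean expression (lower median if even)."""
    order = sorted(candidates, key=lambda p: (means[p], candidates.index(p)))
    return order[(len(order) - 1) // 2]


def translate_signature(sig: Signature, target_annot: ProbeAnnotation,
                        X_target: ExpressionMatrix) -> MappedSignature:
    """Map each unique signature gene to one probe of the target platform.

    Redundant target probes are resolved by the intermediate-expression rule
    computed over ``X_target``'s samples (log2 scale required).  Signature
    probes without a gene symbol cannot cross platforms and are ignored.
    """
    if X_target.scale != SCALE_LOG2:
        raise DomainError("target matrix must be on the log2 scale")
    if all(not s for s, _ in target_annot.entries.values()):
        raise DomainError("target annotation carries no gene symbols")
    target_idx = X_target.probe_index()
    # symbol -> target probes present in the expression matrix
    by_symbol = {}
    for probe, (symbol, _) in target_annot.entries.items():
        if symbol and probe in target_idx:
            by_symbol.setdefault(symbol, []).append(probe)

    # representative source probe per gene = first (best-ranked) occurrence
    source_rep = {}
    for row in sig.table.itertuples(index=False):
        if row.gene_symbol and row.gene_symbol not in source_rep:
            source_rep[row.gene_symbol] = row.probe_id

    pairs, genes, unmapped, log = {}, {}, [], {}
    mean_expr = X_target.values.mean(axis=1)
    for gene, src_probe in source_rep.items():
        candidates = by_symbol.get(gene, [])
        if not candidates:
            unmapped.append(gene)
            continue
        means = {p: float(mean_expr[target_idx[p]]) for p in candidates}
        chosen = _intermediate_probe(candidates, means)
        pairs[src_probe] = chosen
        genes[gene] = (src_probe, chosen)
        log[gene] = GeneResolution(gene, list(candidates), chosen, means)
    return MappedSignature(pairs, genes, unmapped, log)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Standardize each row (gene) to zero mean, unit variance."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


@dataclass
class ExternalValidation:
    per_cost: dict          # cost -> Metrics
    probabilities: dict     # cost -> {sample_id: p(positive)}
    genes: list             # gene order used for the feature pairing


def external_validate(X_train: ExpressionMatrix, y_train: LabelVector,
                      sig: Signature, mapping: MappedSignature,
                      X_ext: ExpressionMatrix, y_ext: LabelVector,
                      cost_grid=(1.0, 2.0, 10.0), seed: int = 0) -> ExternalValidation:
    """Train on the source cohort, predict the external cohort, per cost.

    Features are the mapped genes, paired source-probe-to-target-probe, and
    each gene is z-scored within each data set independently.  For every
    cost in ``cost_grid`` a linear SVM with logit calibration is fitted on
    the (standardized) training side only; external samples are predicted,
    and overall plus per-class accuracy is reported.
    """
    if not mapping.genes:
        raise DomainError("mapping is empty; nothing to validate")
    gene_order = list(mapping.genes)
    train_idx = X_train.probe_index()
    ext_idx = X_ext.probe_index()
    for gene, (sp, tp) in mapping.genes.items():
        if sp not in train_idx:
            raise DomainError(f"source probe {sp!r} for gene {gene!r} absent "
                              "from the training matrix")
        if tp not in ext_idx:
            raise DomainError(f"target probe {tp!r} for gene {gene!r} absent "
                              "from the external matrix")
    src_rows = [train_idx[mapping.genes[g][0]] for g in gene_order]
    tgt_rows = [ext_idx[mapping.genes[g][1]] for g in gene_order]
    Ztr = _zscore_rows(X_train.values[src_rows]).T   # samples x genes
    Zex = _zscore_rows(X_ext.values[tgt_rows]).T
    ytr = y_train.y(X_train.sample_ids)
    yex = y_ext.y(X_ext.sample_ids)

    per_cost, probabilities = {}, {}
    for cost in cost_grid:
        spec = clf.ClassifierSpec("SVM_linear", cost=float(cost))
        model = clf.train_linear_svm(Ztr, ytr, spec, feature_ids=gene_order)
        model = clf.calibrate_logit(model, Ztr, ytr, seed=seed)
        probs = np.array([clf.predict_proba(model, x) for x in Zex])
        pred = probs > 0.5
        tp = int((pred & yex).sum())
        fn = int((~pred & yex).sum())
        tn = int((~pred & ~yex).sum())
        fp = int((pred & ~yex).sum())
        per_cost[float(cost)] = confusion_metrics(tp, fn, tn, fp)
        probabilities[float(cost)] = dict(zip(X_ext.sample_ids, probs.tolist()))
    return ExternalValidation(per_cost, probabilities, gene_order)
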