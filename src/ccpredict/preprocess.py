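"""Pre-filters applied before classifier training.

Two unsupervised filters mirror standard microarray practice: keep only
probes with functional annotation (protein-coding or non-coding), and drop
probes whose average intensity across all samples sits at or below an
empirical background floor (10 on the unlogged scale by default).  Neither
filter looks at class labels, so both may be applied once, up front, without
biasing cross-validation.

External validation data arrive as unlogged normalized intensities and are
log2-transformed before use; :func:`log2_transform` does that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import (
    SCALE_LOG2,
    SCALE_UNLOGGED,
    DomainError,
    ExpressionMatrix,
    ProbeAnnotation,
)


@dataclass
class FilterConfig:
    """Pre-filter settings.

    ``background_threshold`` is an intensity on the unlogged scale; a probe
    is kept only if its mean across all samples is strictly above it.
    """

    background_threshold: float = 10.0
    require_annotation: bool = True

    def __post_init__(self):
        if self.background_threshold <= 0:
            raise DomainError("background_threshold must be > 0")


def filter_annotated(X: ExpressionMatrix, annot: ProbeAnnotation) -> ExpressionMatrix:
    """Keep only probes with functional annotation (coding or non-coding).

    Every probe of ``X`` must be present in ``annot``; probes missing from
    the annotation are an error, not silently dropped.
    """
    missing = [p for p in X.probe_ids if p not in annot]
    if missing:
        raise KeyError(
            f"{len(missing)} probes absent from annotation, e.g. {missing[:5]}"
        )
    keep = [p for p in X.probe_ids if annot.is_annotated(p)]
    return X.subset_probes(keep)


def filter_above_background(X: ExpressionMatrix, cfg: FilterConfig = None) -> ExpressionMatrix:
    """Keep probes whose mean intensity is strictly above the background floor.

    Defined on the unlogged scale only; the mean is taken across all samples
    of the matrix (not per class), so the filter is label-free.
    """
    if cfg is None:
        cfg = FilterConfig()
    if X.scale != SCALE_UNLOGGED:
        raise DomainError(
            "background filtering is defined on the unlogged scale; "
            f"got scale={X.scale!r}"
        )
    means = X.values.mean(axis=1)
    keep = [p for p, m in zip(X.probe_ids, means) if m > cfg.background_threshold]
    return X.subset_probes(keep)


def log2_transform(X: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return log2(value + offset) with the scale flag set to ``log2``."""
    if X.scale != SCALE_UNLOGGED:
        raise DomainError("log2_transform expects an unlogged matrix")
    shifted = X.values + offset
    if (shifted <= 0).any():
        raise DomainError(
            "non-positive intensity under log2; supply a positive offset"
        )
    return ExpressionMatrix(X.probe_ids, X.sample_ids, np.log2(shifted), SCALE_LOG2)


def unlog2_transform(X: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform` (2**value - offset)."""
    if X.scale != SCALE_LOG2:
        raise DomainError("unlog2_transform expects a log2 matrix")
    values = np.exp2(X.values) - offset
    return ExpressionMatrix(X.probe_ids, X.sample_ids, values, SCALE_UNLOGGED)
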