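"""End-to-end orchestration: filter -> grid CV -> final model -> permutation
-> ROC -> cross-platform validation, with a machine-readable report.

:func:`run_study` drives the whole analysis on in-memory objects and returns
a report dictionary plus the artifacts (signature, CV result, ROC,
permutation, external validation).  :func:`run_full_pipeline` is the
file-based wrapper used by the command line: it loads the TSV inputs named
in a :class:`PipelineConfig`, runs the study, and writes every artifact to
the output directory.

The report echoes the configuration, seeds and input digests, so any number
it contains can be recomputed from the inputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers as clf
from . import cross_platform, significance
from .expression_io import (
    ExpressionMatrix,
    LabelVector,
    ProbeAnnotation,
    read_annotation,
    read_expression_matrix,
    read_labels,
    write_signature,
)
from .nested_cv import (
    DEFAULT_P_GRID,
    FeatureSelectionConfig,
    choose_optimal,
    final_signature,
    loocv,
    loocv_grid,
)
from .preprocess import FilterConfig, filter_above_background, filter_annotated

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

# the model-selection families crossed with the p-value grid
DEFAULT_ALGORITHM_TEMPLATES = (
    ("dLDA", {}),
    ("kNN", {"k": 3}),
    ("SVM_linear", {"cost": 1.0}),
)


class StageError(RuntimeError):
    """An analysis stage failed; names the stage and the offending input."""


def build_spec_grid(templates=DEFAULT_ALGORITHM_TEMPLATES,
                    p_grid=DEFAULT_P_GRID) -> list:
    """Cross the algorithm templates with the p-value cutoffs."""
    return [clf.ClassifierSpec(alg, p_cutoff=p, **kw)
            for alg, kw in templates for p in p_grid]


def _digest(X: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\x00".join(map(str, X.probe_ids)).encode())
    h.update("\x00".join(map(str, X.sample_ids)).encode())
    h.update(np.ascontiguousarray(X.values).tobytes())
    return h.hexdigest()[:16]


@dataclass
class StudyResult:
    report: dict
    filtered: ExpressionMatrix
    grid: list                    # [(spec, CVResult)]
    chosen_spec: clf.ClassifierSpec
    chosen_cv: "object"           # CVResult with probabilities
    signature: "object"
    permutation: "object"
    roc: "object"
    external: "object" = None
    mapping: "object" = None


def run_study(X: ExpressionMatrix, annot: ProbeAnnotation, labels: LabelVector,
              *, filter_cfg: FilterConfig = None,
              fs_cfg: FeatureSelectionConfig = None,
              algorithm_templates=DEFAULT_ALGORITHM_TEMPLATES,
              n_perm: int = 1000, seed: int = 0,
              external: tuple = None, cost_grid=(1.0, 2.0, 10.0)) -> StudyResult:
    """Run the complete analysis on in-memory objects.

    ``external``, if given, is a tuple ``(X_ext, annot_ext, y_ext)`` with
    ``X_ext`` on the log2 scale.  Stages run in order: annotation filter,
    background filter, LOOCV over the full algorithm x p-cutoff grid,
    optimum choice, final signature, permutation test of the chosen spec,
    ROC on the chosen model's LOOCV probabilities, and (optionally)
    signature translation plus external validation per cost.
    """
    filter_cfg = filter_cfg or FilterConfig()
    fs_cfg = fs_cfg or FeatureSelectionConfig()
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "inputs": {
            "matrix_digest": _digest(X),
            "n_probes": X.n_probes,
            "n_samples": X.n_samples,
            "classes": {labels.positive_name: labels.counts(X.sample_ids)[0],
                        labels.negative_name: labels.counts(X.sample_ids)[1]},
        },
        "config": {
            "background_threshold": filter_cfg.background_threshold,
            "require_annotation": filter_cfg.require_annotation,
            "p_grid": list(fs_cfg.p_grid),
            "t_test": fs_cfg.test,
            "algorithms": [dict(algorithm=a, **kw) for a, kw in algorithm_templates],
            "n_perm": n_perm,
            "cost_grid": list(cost_grid),
        },
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("filter_annotated")
        Xa = filter_annotated(X, annot) if filter_cfg.require_annotation else X
        name = stage("filter_above_background")
        Xf = filter_above_background(Xa, filter_cfg)
        report["filtering"] = {
            "probes_in": X.n_probes,
            "after_annotation": Xa.n_probes,
            "after_background": Xf.n_probes,
        }

        name = stage("loocv_grid")
        specs = build_spec_grid(algorithm_templates, fs_cfg.p_grid)
        grid = loocv_grid(Xf, labels, specs, seed=seed, compute_proba=False,
                          test=fs_cfg.test)
        report["model_grid"] = [
            {
                "algorithm": s.algorithm,
                "model": s.label(),
                "p_cutoff": s.p_cutoff,
                "accuracy": cv.accuracy,
                "median_n_selected": cv.median_n_selected,
            }
            for s, cv in grid
        ]

        name = stage("choose_optimal")
        chosen_spec, _ = choose_optimal(grid)
        name = stage("loocv_chosen")
        chosen_cv = loocv(Xf, labels, chosen_spec, seed=seed,
                          compute_proba=True, test=fs_cfg.test)
        report["chosen"] = {
            "model": chosen_spec.label(),
            "p_cutoff": chosen_spec.p_cutoff,
            "accuracy": chosen_cv.accuracy,
            "per_class_accuracy": chosen_cv.per_class_accuracy,
            "metrics": chosen_cv.metrics.as_dict(),
        }

        name = stage("final_signature")
        sig = final_signature(Xf, labels, chosen_spec.p_cutoff, chosen_cv,
                              annot=annot, test=fs_cfg.test)
        report["signature"] = {
            "n_probes": len(sig),
            "n_unique_genes": len(sig.unique_genes),
            "n_support_100": int((sig.table["cv_support"] == 100.0).sum()),
        }

        name = stage("permutation_test")
        perm = significance.permutation_test(
            Xf, labels, chosen_spec, n_perm=n_perm, seed=seed, test=fs_cfg.test)
        report["permutation"] = perm.as_dict()

        name = stage("roc")
        probs = [f.proba for f in chosen_cv.per_fold]
        roc = significance.roc_curve(probs, labels, Xf.sample_ids)
        report["roc"] = {"auc": roc.auc}

        external_result = mapping = None
        if external is not None:
            name = stage("translate_signature")
            X_ext, annot_ext, y_ext = external
            mapping = cross_platform.translate_signature(sig, annot_ext, X_ext)
            report["translation"] = {
                "n_genes_source": len(sig.unique_genes),
                "n_genes_mapped": mapping.n_mapped,
                "unmapped_genes": list(mapping.unmapped_genes),
            }
            name = stage("external_validate")
            external_result = cross_platform.external_validate(
                Xf, labels, sig, mapping, X_ext, y_ext,
                cost_grid=cost_grid, seed=seed)
            report["external"] = {
                f"cost_{c:g}": m.as_dict()
                for c, m in external_result.per_cost.items()
            }
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc

    return StudyResult(report, Xf, grid, chosen_spec, chosen_cv, sig, perm,
                       roc, external_result, mapping)


# ---------------------------------------------------------------------------
# file-based wrapper


@dataclass
class PipelineConfig:
    """Paths and parameters for a file-driven pipeline run."""

    matrix: str
    annotation: str
    labels: str
    out_dir: str
    external_matrix: str = None
    external_annotation: str = None
    external_labels: str = None
    positive_name: str = "LB"
    negative_name: str = "NP"
    ext_positive_name: str = "B"
    ext_negative_name: str = "EP"
    background_threshold: float = 10.0
    require_annotation: bool = True
    transpose: bool = False  # training matrix laid out samples-in-rows
    p_grid: tuple = DEFAULT_P_GRID
    t_test: str = "student"
    n_perm: int = 1000
    seed: int = 0
    cost_grid: tuple = (1.0, 2.0, 10.0)
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float)
        fh.write("\n")


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Load the configured inputs, run the study, write all artifacts.

    Outputs under ``cfg.out_dir``: ``report.json``, ``model_grid.tsv``,
    ``signature.tsv``, ``cv_folds.tsv``, ``roc_points.tsv``,
    ``permutation_null.tsv`` and, when external data are configured,
    ``mapping.tsv`` and ``external_probabilities.tsv``.  An existing
    non-empty output directory is refused unless ``cfg.force``.
    """
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.force:
        raise StageError(
            f"output directory {out} is not empty; pass force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    X = read_expression_matrix(cfg.matrix, transpose=cfg.transpose)
    annot = read_annotation(cfg.annotation)
    labels = read_labels(cfg.labels, cfg.positive_name, cfg.negative_name)
    external = None
    if cfg.external_matrix:
        X_ext = read_expression_matrix(cfg.external_matrix, scale="log2")
        annot_ext = read_annotation(cfg.external_annotation)
        y_ext = read_labels(cfg.external_labels, cfg.ext_positive_name,
                            cfg.ext_negative_name)
        external = (X_ext, annot_ext, y_ext)

    result = run_study(
        X, annot, labels,
        filter_cfg=FilterConfig(cfg.background_threshold, cfg.require_annotation),
        fs_cfg=FeatureSelectionConfig(tuple(cfg.p_grid), cfg.t_test),
        n_perm=cfg.n_perm, seed=cfg.seed, external=external,
        cost_grid=tuple(cfg.cost_grid),
    )

    pd.DataFrame(result.report["model_grid"]).to_csv(
        out / "model_grid.tsv", sep="\t", index=False)
    write_signature(result.signature, out / "signature.tsv")
    result.chosen_cv.fold_table().to_csv(out / "cv_folds.tsv", sep="\t",
                                         index=False)
    pd.DataFrame({"fpr": result.roc.fpr, "tpr": result.roc.tpr}).to_csv(
        out / "roc_points.tsv", sep="\t", index=False)
    pd.DataFrame({"null_error": result.permutation.null_errors}).to_csv(
        out / "permutation_null.tsv", sep="\t", index=False)
    if result.mapping is not None:
        rows = []
        for gene, (sp, tp) in result.mapping.genes.items():
            res = result.mapping.resolution_log[gene]
            rows.append((gene, sp, tp, len(res.candidates),
                         ";".join(res.candidates)))
        for gene in result.mapping.unmapped_genes:
            rows.append((gene, "", "", 0, ""))
        pd.DataFrame(rows, columns=["gene", "source_probe", "target_probe",
                                    "n_candidates", "candidates"]).to_csv(
            out / "mapping.tsv", sep="\t", index=False)
        prob_rows = [
            (f"{c:g}", s, p)
            for c, sample_probs in result.external.probabilities.items()
            for s, p in sample_probs.items()
        ]
        pd.DataFrame(prob_rows, columns=["cost", "sample_id", "p_positive"]
                     ).to_csv(out / "external_probabilities.tsv", sep="\t",
                              index=False)
    _write_report(result.report, out / "report.json")
    return result.report
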