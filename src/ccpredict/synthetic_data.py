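"""Synthetic two-class microarray data with planted differential expression.

The generator emulates the statistical shape of a small case-control
competence study: two classes of order 10-15 samples, tens of thousands of
probes, a fraction of probes below the background intensity floor, a
fraction without functional annotation, log-normal baseline intensities,
large within-group variability, and a small set of planted differentially
expressed probes with balanced up/down directions.  A companion generator
derives a second "platform" for the same biology — gene-symbol annotation,
1..k redundant probes per gene with probe-specific affinities, an
incomplete gene overlap, a different global intensity scale, and a fresh
sample cohort — so cross-platform translation and external validation can
be exercised end to end without any download.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import (
    SCALE_LOG2,
    STATUS_CODING,
    STATUS_NONCODING,
    STATUS_UNANNOTATED,
    DomainError,
    ExpressionMatrix,
    LabelVector,
    ProbeAnnotation,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the shape of the cumulus-cell training cohort: 12
    positive vs 15 negative samples, 20,000 probes of which 15% lack
    annotation and 10% sit below the background floor of 10 (unlogged
    intensity units), 30 planted probes at fold change 4, and within-group
    coefficient of variation 0.3 (multiplicative log-normal noise).
    ``baseline_log_mean``/``baseline_log_sd`` parameterize the log-normal
    baseline intensity above the background floor (natural-log scale).
    """

    n_pos: int = 12
    n_neg: int = 15
    n_probes: int = 20000
    frac_unannotated: float = 0.15
    frac_background: float = 0.10
    n_de: int = 30
    fold_change: float = 4.0
    cv_within: float = 0.3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.2
    background_threshold: float = 10.0
    frac_noncoding: float = 0.25
    probes_per_gene_target: tuple = (1, 2, 3)
    frac_genes_missing_target: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_unannotated", "frac_background",
                     "frac_genes_missing_target", "frac_noncoding"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.fold_change <= 0:
            raise DomainError("fold_change must be > 0")
        if self.cv_within < 0:
            raise DomainError("cv_within must be >= 0")
        if self.n_pos < 1 or self.n_neg < 1 or self.n_probes < 1:
            raise DomainError("sample and probe counts must be positive")
        n_annotated = self.n_probes - round(self.frac_unannotated * self.n_probes)
        if self.n_de > n_annotated:
            raise DomainError(
                f"n_de={self.n_de} exceeds the {n_annotated} annotated probes"
            )
        self.probes_per_gene_target = tuple(int(k) for k in self.probes_per_gene_target)
        if any(k < 1 for k in self.probes_per_gene_target):
            raise DomainError("probes_per_gene_target entries must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: the DE probes, their directions, and the gene map."""

    de_probe_ids: set
    de_direction: dict   # probe -> "up" | "down" (in the positive class)
    gene_map: dict       # annotated probe -> gene symbol


def _lognormal_noise(rng, cv, shape):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def simulate_study(cfg: SimulationConfig):
    """Generate (ExpressionMatrix, ProbeAnnotation, LabelVector, GroundTruth).

    Probe baseline intensities are log-normal above the background floor;
    a configured fraction of probes is drawn with means below the floor.
    Planted probes (always annotated, never background) have their positive
    -class mean multiplied by ``fold_change`` (half up, half down).  Samples
    carry multiplicative log-normal noise at ``cv_within``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probe_ids = [f"P{i:05d}" for i in range(n)]

    order = rng.permutation(n)
    n_un = round(cfg.frac_unannotated * n)
    unannotated = set(order[:n_un].tolist())
    annotated = order[n_un:]

    n_bg = round(cfg.frac_background * n)
    bg_pool = rng.permutation(n)
    background = set(bg_pool[:n_bg].tolist())

    de_pool = np.array([i for i in annotated if i not in background])
    de_idx = rng.choice(de_pool, size=cfg.n_de, replace=False)
    n_down = cfg.n_de // 2
    directions = np.array(["down"] * n_down + ["up"] * (cfg.n_de - n_down))
    rng.shuffle(directions)

    base = np.empty(n)
    is_bg = np.zeros(n, dtype=bool)
    is_bg[list(background)] = True
    n_above = int((~is_bg).sum())
    base[~is_bg] = cfg.background_threshold + rng.lognormal(
        cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_above)
    base[is_bg] = rng.uniform(1.0, 0.95 * cfg.background_threshold,
                              size=int(is_bg.sum()))

    mean_pos = base.copy()
    for i, d in zip(de_idx, directions):
        mean_pos[i] = base[i] * cfg.fold_change if d == "up" else base[i] / cfg.fold_change

    n_samp = cfg.n_pos + cfg.n_neg
    means = np.empty((n, n_samp))
    means[:, :cfg.n_pos] = mean_pos[:, None]
    means[:, cfg.n_pos:] = base[:, None]
    values = means * _lognormal_noise(rng, cfg.cv_within, (n, n_samp))

    sample_ids = ([f"LB_{j + 1:02d}" for j in range(cfg.n_pos)]
                  + [f"NP_{j + 1:02d}" for j in range(cfg.n_neg)])
    labels = LabelVector(
        {s: ("LB" if j < cfg.n_pos else "NP") for j, s in enumerate(sample_ids)},
        positive_name="LB", negative_name="NP",
    )

    entries = {}
    gene_map = {}
    gene_counter = 0
    noncoding = rng.random(n) < cfg.frac_noncoding
    for i in range(n):
        pid = probe_ids[i]
        if i in unannotated:
            entries[pid] = ("", STATUS_UNANNOTATED)
        else:
            symbol = f"GENE{gene_counter:05d}"
            gene_counter += 1
            status = STATUS_NONCODING if noncoding[i] else STATUS_CODING
            entries[pid] = (symbol, status)
            gene_map[pid] = symbol

    X = ExpressionMatrix(probe_ids, sample_ids, values)
    annot = ProbeAnnotation(entries)
    truth = GroundTruth(
        de_probe_ids={probe_ids[i] for i in de_idx},
        de_direction={probe_ids[i]: d for i, d in zip(de_idx, directions)},
        gene_map=gene_map,
    )
    return X, annot, labels, truth


def simulate_external_platform(X: ExpressionMatrix, truth: GroundTruth,
                               cfg: SimulationConfig, scale_factor: float = 0.25):
    """Second-platform cohort for the same biology, as (matrix, annot, labels).

    Every annotated source gene (minus a dropped fraction) is represented by
    1..k redundant probes with log-normal probe affinities.  A fresh sample
    cohort (same class sizes, endpoint names "B"/"EP") is drawn from the
    same class-effect model: planted genes keep their direction and fold
    change.  Intensities are emitted on a different global scale and then
    log2-transformed, emulating the platform switch.
    """
    rng = np.random.default_rng([cfg.seed, 104729])  # independent stream
    de_genes = {truth.gene_map[p]: truth.de_direction[p]
                for p in truth.de_probe_ids if p in truth.gene_map}
    genes = sorted(set(truth.gene_map.values()))
    n_drop = round(cfg.frac_genes_missing_target * len(genes))
    dropped = set(rng.choice(np.array(genes, dtype=object),
                             size=n_drop, replace=False).tolist())
    kept = [g for g in genes if g not in dropped]

    probe_ids, probe_gene, probe_base = [], [], []
    for g in kept:
        k = int(rng.choice(cfg.probes_per_gene_target))
        gene_base = cfg.background_threshold + rng.lognormal(
            cfg.baseline_log_mean, cfg.baseline_log_sd)
        affinities = rng.lognormal(0.0, 0.4, size=k)
        for j in range(k):
            probe_ids.append(f"A_{g}_{j + 1}")
            probe_gene.append(g)
            probe_base.append(gene_base * affinities[j])
    probe_base = np.asarray(probe_base)

    n_probes = len(probe_ids)
    n_samp = cfg.n_pos + cfg.n_neg
    mean_pos = probe_base.copy()
    for i, g in enumerate(probe_gene):
        d = de_genes.get(g)
        if d == "up":
            mean_pos[i] *= cfg.fold_change
        elif d == "down":
            mean_pos[i] /= cfg.fold_change
    means = np.empty((n_probes, n_samp))
    means[:, :cfg.n_pos] = mean_pos[:, None]
    means[:, cfg.n_pos:] = probe_base[:, None]
    values = scale_factor * means * _lognormal_noise(rng, cfg.cv_within,
                                                     (n_probes, n_samp))

    sample_ids = ([f"B_{j + 1:02d}" for j in range(cfg.n_pos)]
                  + [f"EP_{j + 1:02d}" for j in range(cfg.n_neg)])
    labels = LabelVector(
        {s: ("B" if j < cfg.n_pos else "EP") for j, s in enumerate(sample_ids)},
        positive_name="B", negative_name="EP",
    )
    annot = ProbeAnnotation({p: (g, STATUS_CODING)
                             for p, g in zip(probe_ids, probe_gene)})
    Xt = ExpressionMatrix(probe_ids, sample_ids, np.log2(values), SCALE_LOG2)
    return Xt, annot, labels
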