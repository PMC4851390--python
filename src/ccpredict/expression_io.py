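"""Core data containers and tab-separated I/O.

Every stage of the pipeline passes around four objects defined here: an
:class:`ExpressionMatrix` of non-negative normalized probe intensities
(probes in rows, samples in columns), a :class:`ProbeAnnotation` mapping
probe ids to gene symbols and coding status, a :class:`LabelVector` with the
binary outcome of each sample (e.g. live birth "LB" vs no pregnancy "NP"),
and a :class:`Signature` — the ordered list of selected probes with their
test statistics, fold changes and cross-validation support, which is the
portable artifact that crosses array platforms.

All on-disk formats are UTF-8 tab-separated text with a mandatory header
row.  Matrices must be complete: an empty cell is a parse error, not a
missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALE_UNLOGGED = "unlogged"
SCALE_LOG2 = "log2"
SCALES = (SCALE_UNLOGGED, SCALE_LOG2)

STATUS_CODING = "protein_coding"
STATUS_NONCODING = "non_coding"
STATUS_UNANNOTATED = "unannotated"
STATUSES = (STATUS_CODING, STATUS_NONCODING, STATUS_UNANNOTATED)

SIGNATURE_COLUMNS = (
    "probe_id",
    "gene_symbol",
    "t_statistic",
    "p_value",
    "fold_change",
    "cv_support",
)


class FormatError(ValueError):
    """Structural problem in an input file (duplicate ids, missing columns)."""


class ParseError(ValueError):
    """A cell or token that cannot be interpreted; carries coordinates."""


class DomainError(ValueError):
    """A value outside the domain the operation is defined on."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensity matrix.

    Parameters
    ----------
    probe_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        2-D float array of shape ``(len(probe_ids), len(sample_ids))``.
    scale
        ``"unlogged"`` (non-negative normalized intensities) or ``"log2"``.
    """

    probe_ids: list
    sample_ids: list
    values: np.ndarray
    scale: str = SCALE_UNLOGGED

    def __post_init__(self):
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise DomainError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise DomainError("matrix contains non-finite values")
        if self.scale == SCALE_UNLOGGED and (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise DomainError(
                f"negative intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} on the unlogged scale"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        """Restrict to the given probes, in the given order."""
        idx = self.probe_index()
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), self.sample_ids, self.values[rows], self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.probe_ids, list(sample_ids), self.values[:, cols], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and self.scale == other.scale
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ProbeAnnotation:
    """Probe -> (gene symbol, coding status) map.

    ``status`` is one of ``protein_coding``, ``non_coding``, ``unannotated``.
    A probe is ``unannotated`` exactly when it carries no functional
    annotation; a ``protein_coding`` probe must carry a gene symbol.
    """

    entries: dict  # probe_id -> (gene_symbol, status)

    def __post_init__(self):
        for probe, (symbol, status) in self.entries.items():
            if status not in STATUSES:
                raise ParseError(f"unknown status {status!r} for probe {probe!r}")
            if status == STATUS_CODING and not symbol:
                raise FormatError(f"protein_coding probe {probe!r} lacks a gene symbol")

    def __contains__(self, probe) -> bool:
        return probe in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def symbol(self, probe) -> str:
        return self.entries[probe][0]

    def status(self, probe) -> str:
        return self.entries[probe][1]

    def is_annotated(self, probe) -> bool:
        return self.entries[probe][1] != STATUS_UNANNOTATED

    def probes_for_symbol(self, symbol: str) -> list:
        """All probes carrying the given gene symbol, in entry order."""
        return [p for p, (s, _) in self.entries.items() if s == symbol and symbol]


@dataclass
class LabelVector:
    """Binary class assignment of samples.

    ``labels`` maps every sample id to either ``positive_name`` (e.g. "LB",
    the live-birth class, or "B", blastocyst) or ``negative_name`` ("NP" /
    "EP").
    """

    labels: dict  # sample_id -> class name
    positive_name: str = "LB"
    negative_name: str = "NP"

    def __post_init__(self):
        if self.positive_name == self.negative_name:
            raise FormatError("positive and negative class names must differ")
        for s, c in self.labels.items():
            if c not in (self.positive_name, self.negative_name):
                raise FormatError(
                    f"sample {s!r} has label {c!r}, expected "
                    f"{self.positive_name!r} or {self.negative_name!r}"
                )

    def is_positive(self, sample) -> bool:
        return self.labels[sample] == self.positive_name

    def y(self, sample_ids) -> np.ndarray:
        """Boolean vector (True = positive class) aligned to ``sample_ids``."""
        return np.array([self.is_positive(s) for s in sample_ids], dtype=bool)

    def counts(self, sample_ids=None) -> tuple:
        ids = sample_ids if sample_ids is not None else list(self.labels)
        y = self.y(ids)
        return int(y.sum()), int((~y).sum())

    def require_both_classes(self, sample_ids=None) -> None:
        n_pos, n_neg = self.counts(sample_ids)
        if n_pos == 0 or n_neg == 0:
            raise DomainError(
                f"both classes must be non-empty (got {n_pos} "
                f"{self.positive_name}, {n_neg} {self.negative_name})"
            )


@dataclass
class Signature:
    """Ordered probe list with per-probe statistics.

    Wraps a DataFrame with columns ``probe_id, gene_symbol, t_statistic,
    p_value, fold_change, cv_support`` (support as a percentage in [0, 100]).
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"signature table missing columns: {missing}")
        self.table = self.table.loc[:, list(SIGNATURE_COLUMNS)].reset_index(drop=True)
        _check_unique(self.table["probe_id"], "signature probe")
        p = self.table["p_value"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise DomainError("p_value outside [0, 1]")
        sup = self.table["cv_support"].to_numpy(dtype=float)
        if ((sup < 0) | (sup > 100)).any():
            raise DomainError("cv_support outside [0, 100]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list:
        return list(self.table["probe_id"])

    @property
    def unique_genes(self) -> list:
        """Unique non-empty gene symbols, in first-appearance order."""
        seen, out = set(), []
        for s in self.table["gene_symbol"]:
            if s and s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def equals(self, other: "Signature") -> bool:
        a, b = self.table, other.table
        if list(a["probe_id"]) != list(b["probe_id"]):
            return False
        if list(a["gene_symbol"]) != list(b["gene_symbol"]):
            return False
        num = ["t_statistic", "p_value", "fold_change", "cv_support"]
        return np.array_equal(a[num].to_numpy(float), b[num].to_numpy(float))


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, scale: str = SCALE_UNLOGGED,
                           transpose: bool = False) -> ExpressionMatrix:
    """Read a probe-by-sample TSV (first column probe ids, header sample ids).

    Row and column order are preserved from the file.  Duplicate ids raise
    :class:`FormatError`; a non-numeric or empty cell raises
    :class:`ParseError` naming the offending probe and sample.  Files laid
    out samples-in-rows can be read with ``transpose=True``.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a header with at least one sample column")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    raw = pd.read_csv(
        path, sep="\t", skiprows=1, header=None, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    probe_ids = [str(p) for p in raw.index]
    _check_unique(probe_ids, "probe")
    if raw.shape[1] != len(sample_ids):
        raise FormatError(
            f"{path}: {raw.shape[1]} data columns but {len(sample_ids)} sample ids"
        )
    cells = raw.to_numpy()
    values = np.empty(cells.shape, dtype=float)
    for j in range(cells.shape[1]):
        col = cells[:, j]
        try:
            values[:, j] = col.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(col):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at probe "
                        f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
            raise
        bad = np.flatnonzero(np.isnan(values[:, j]))
        if bad.size:  # explicit NaN tokens: matrices must be complete
            i = int(bad[0])
            raise ParseError(
                f"{path}: missing/NaN cell at probe {probe_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
    if transpose:
        return ExpressionMatrix(sample_ids, probe_ids, values.T, scale)
    return ExpressionMatrix(probe_ids, sample_ids, values, scale)


def write_expression_matrix(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path) -> ProbeAnnotation:
    """Read a probe annotation TSV with columns probe_id, gene_symbol, status."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    required = ("probe_id", "gene_symbol", "status")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    entries = {}
    for row in df.itertuples(index=False):
        probe = row.probe_id
        if probe in entries:
            raise FormatError(f"{path}: duplicate probe id {probe!r}")
        if row.status not in STATUSES:
            raise ParseError(
                f"{path}: unknown status {row.status!r} for probe {probe!r} "
                f"(expected one of {STATUSES})"
            )
        entries[probe] = (row.gene_symbol, row.status)
    return ProbeAnnotation(entries)


def write_annotation(annot: ProbeAnnotation, path) -> None:
    df = pd.DataFrame(
        [(p, s, st) for p, (s, st) in annot.entries.items()],
        columns=["probe_id", "gene_symbol", "status"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path, positive_name: str = "LB", negative_name: str = "NP") -> LabelVector:
    """Read a two-column TSV (sample_id, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: labels file missing column {col!r}")
    labels = {}
    for row in df.itertuples(index=False):
        if row.sample_id in labels:
            raise FormatError(f"{path}: duplicate sample id {row.sample_id!r}")
        labels[row.sample_id] = row.label
    return LabelVector(labels, positive_name, negative_name)


def write_labels(labels: LabelVector, path) -> None:
    df = pd.DataFrame(list(labels.labels.items()), columns=["sample_id", "label"])
    df.to_csv(path, sep="\t", index=False)


def write_signature(sig: Signature, path) -> None:
    """Write a signature TSV; re-reading reproduces the signature exactly.

    Numeric columns are serialized with full (shortest round-trip) precision,
    so e.g. cv_support 88.9 and 100.0 remain distinguishable.
    """
    if len(sig) == 0:
        raise DomainError("refusing to write an empty signature")
    sig.table.to_csv(path, sep="\t", index=False)


def read_signature(path) -> Signature:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str},
                     keep_default_na=False, na_values=[])
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: signature missing columns {missing}")
    for col in ("t_statistic", "p_value", "fold_change", "cv_support"):
        df[col] = pd.to_numeric(df[col])
    return Signature(df)
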