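"""Domain types and I/O for longitudinal two-class expression studies.

The central object is :class:`LongitudinalExpressionSet`: a complete
genes x subjects x timepoints array with a binary phenotype per subject.
Gene sets are plain named lists of gene identifiers (GMT dialect) that
must be aligned against the measured genes before analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalExpressionSet",
    "GeneSetCollection",
    "Signature",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "align_gene_sets",
]


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass
class LongitudinalExpressionSet:
    """Complete-case longitudinal expression data with a binary phenotype.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_subjects, n_timepoints)``; every cell
        must be finite (complete-case design).
    genes, subjects, timepoints
        Axis labels. Time labels are ordered categorical tokens shared by
        all subjects; they are never interpreted numerically.
    phenotype
        Mapping ``subject -> label`` with exactly two distinct labels,
        each carried by at least two subjects.
    positive_label
        Which phenotype level is treated as the "diseased"/positive class.
        Defaults to the last label in sorted order.
    """

    values: np.ndarray
    genes: list[str]
    subjects: list[str]
    timepoints: list[str]
    phenotype: dict[str, object]
    positive_label: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = list(self.genes)
        self.subjects = list(self.subjects)
        self.timepoints = [str(t) for t in self.timepoints]
        if self.values.shape != (len(self.genes), len(self.subjects), len(self.timepoints)):
            raise DataError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.genes)}, {len(self.subjects)}, {len(self.timepoints)})"
            )
        for name, axis in (("genes", self.genes), ("subjects", self.subjects),
                           ("timepoints", self.timepoints)):
            if len(set(axis)) != len(axis):
                raise DataError(f"duplicate labels in {name}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite (complete-case design)")
        missing = [s for s in self.subjects if s not in self.phenotype]
        if missing:
            raise DataError(f"subjects missing from phenotype: {missing}")
        self.phenotype = {s: self.phenotype[s] for s in self.subjects}
        levels = sorted({str(v) for v in self.phenotype.values()})
        if len(levels) != 2:
            raise DataError(f"phenotype must have exactly 2 levels, got {levels}")
        counts = pd.Series([str(v) for v in self.phenotype.values()]).value_counts()
        if counts.min() < 2:
            raise DataError(f"each phenotype class needs >=2 subjects, got {dict(counts)}")
        if self.positive_label is None:
            self.positive_label = levels[-1]
        elif str(self.positive_label) not in levels:
            raise DataError(f"positive_label {self.positive_label!r} not among {levels}")
        self.positive_label = str(self.positive_label)

    # -- derived views ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def labels(self) -> np.ndarray:
        """Phenotype labels aligned with ``subjects`` (as strings)."""
        return np.array([str(self.phenotype[s]) for s in self.subjects])

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 for the positive class, 0 otherwise."""
        return (self.labels == self.positive_label).astype(int)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression set") from None

    def timepoint_index(self, timepoint: str) -> int:
        try:
            return self.timepoints.index(str(timepoint))
        except ValueError:
            raise KeyError(f"timepoint {timepoint!r} not in expression set") from None

    def subset_genes(self, genes: Sequence[str]) -> "LongitudinalExpressionSet":
        idx = [self.gene_index(g) for g in genes]
        return LongitudinalExpressionSet(
            self.values[idx], [self.genes[i] for i in idx], self.subjects,
            self.timepoints, dict(self.phenotype), self.positive_label,
        )

    def subset_subjects(self, subjects: Sequence[str]) -> "LongitudinalExpressionSet":
        idx = [self.subjects.index(s) for s in subjects]
        return LongitudinalExpressionSet(
            self.values[:, idx], self.genes, [self.subjects[i] for i in idx],
            self.timepoints, {self.subjects[i]: self.phenotype[self.subjects[i]] for i in idx},
            self.positive_label,
        )

    def slice_timepoint(self, timepoint: str) -> "LongitudinalExpressionSet":
        """Single-timepoint view (still a 3-D set with t = 1)."""
        j = self.timepoint_index(timepoint)
        return LongitudinalExpressionSet(
            self.values[:, :, [j]], self.genes, self.subjects,
            [self.timepoints[j]], dict(self.phenotype), self.positive_label,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicates within a set are disallowed."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise DataError(f"gene set {name!r} contains duplicate members")

    @property
    def K(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class Signature:
    """Selected (gene, timepoint) pairs produced by a selector."""

    entries: list[tuple[str, str]]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.entries = [(str(g), str(t)) for g, t in self.entries]
        if len(set(self.entries)) != len(self.entries):
            raise DataError("duplicate (gene, timepoint) entries in signature")

    @property
    def unique_genes(self) -> int:
        return len({g for g, _ in self.entries})

    def genes_at(self, timepoint: str) -> list[str]:
        return [g for g, t in self.entries if t == str(timepoint)]

    def validate_against(self, expr: LongitudinalExpressionSet) -> None:
        for g, t in self.entries:
            expr.gene_index(g)
            expr.timepoint_index(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "timepoint"]).assign(
            method=self.provenance
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        df = pd.read_csv(path, sep="\t", dtype=str)
        prov = df["method"].iloc[0] if "method" in df.columns and len(df) else "unknown"
        return cls(list(zip(df["gene"], df["timepoint"])), provenance=prov)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are dropped with a warning; lines with
    fewer than three fields raise a parse error naming the line.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: GMT line has <3 fields")
            name, members = fields[0], [f for f in fields[2:] if f]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(f"gene set {name!r} (line {lineno}): duplicate members removed")
            sets[name] = deduped
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_expression(
    path: str | Path,
    pheno_path: str | Path,
    incomplete: str = "drop",
    positive_label: object = None,
) -> LongitudinalExpressionSet:
    """Read a tab-delimited matrix (rows = genes, columns = ``subject:time``)
    together with a two-column subject -> phenotype TSV.

    ``incomplete`` controls subjects lacking some timepoint: ``"drop"``
    removes them with a warning, ``"error"`` raises.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    pheno_df = pd.read_csv(pheno_path, sep="\t", index_col=0, dtype=str)
    phenotype = pheno_df.iloc[:, 0].to_dict()

    pairs = []
    for col in df.columns:
        if ":" not in col:
            raise DataError(f"column {col!r} is not of the form subject:timepoint")
        subj, tp = col.split(":", 1)
        pairs.append((subj, tp))
    subjects = list(dict.fromkeys(s for s, _ in pairs))
    timepoints = list(dict.fromkeys(t for _, t in pairs))

    missing_pheno = [s for s in subjects if s not in phenotype]
    if missing_pheno:
        raise DataError(f"subjects absent from phenotype file: {missing_pheno}")

    have = {p: True for p in pairs}
    complete, dropped = [], []
    for s in subjects:
        if all((s, t) in have for t in timepoints):
            complete.append(s)
        else:
            dropped.append(s)
    if dropped:
        if incomplete == "error":
            raise DataError(f"subjects with incomplete time series: {dropped}")
        warnings.warn(f"dropping subjects with incomplete time series: {dropped}")

    values = np.empty((df.shape[0], len(complete), len(timepoints)))
    for si, s in enumerate(complete):
        for ti, t in enumerate(timepoints):
            values[:, si, ti] = df[f"{s}:{t}"].to_numpy()
    return LongitudinalExpressionSet(
        values, list(df.index.astype(str)), complete, timepoints,
        {s: phenotype[s] for s in complete}, positive_label,
    )


def write_expression(
    expr: LongitudinalExpressionSet, path: str | Path, pheno_path: str | Path
) -> None:
    """Write the matrix and phenotype TSVs; values round-trip bit-exactly."""
    cols = {}
    for si, s in enumerate(expr.subjects):
        for ti, t in enumerate(expr.timepoints):
            cols[f"{s}:{t}"] = expr.values[:, si, ti]
    df = pd.DataFrame(cols, index=pd.Index(expr.genes, name="gene"))
    df.to_csv(path, sep="\t", float_format="%.17g")  # round-trips float64 exactly
    pd.Series({s: expr.phenotype[s] for s in expr.subjects}, name="phenotype").rename_axis(
        "subject"
    ).to_csv(pheno_path, sep="\t")


def align_gene_sets(
    collection: GeneSetCollection,
    expr: LongitudinalExpressionSet,
    min_size: int = 2,
) -> GeneSetCollection:
    """Intersect every set with the measured genes; drop sets below ``min_size``."""
    measured = set(expr.genes)
    aligned: dict[str, list[str]] = {}
    for name, members in collection:
        kept = [g for g in members if g in measured]
        n_lost = len(members) - len(kept)
        if n_lost:
            logger.info("set %s: %d unmeasured member(s) removed", name, n_lost)
        if len(kept) >= min_size:
            aligned[name] = kept
        else:
            logger.info("set %s dropped (size %d < %d)", name, len(kept), min_size)
    if not aligned:
        raise DataError(
            "no gene set survived alignment; the collection does not match the platform"
        )
    return GeneSetCollection(aligned)
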