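"""End-to-end feature selectors built from the SAMGS test and the
reduction engine.

* ``two_level_select`` — SAMGS screen over pathway sets, gene-level
  reduction inside each significant set, then time-point reduction over the
  union of core genes.
* ``longitudinal_select`` — each gene's time profile is its own set: SAMGS
  screen over genes, then time-point reduction per significant gene.
* ``per_timepoint_select`` — classical single-time-point SAMGSR run
  independently on each time slice, results tagged by time point.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .data_model import GeneSetCollection, LongitudinalExpressionSet, Signature
from .reduction import reduce_set
from .sam_core import PermutationEngine, permutation_pvalues

__all__ = [
    "samgs_select",
    "two_level_select",
    "longitudinal_select",
    "per_timepoint_select",
    "select",
]


def _all_cells(expr: LongitudinalExpressionSet, genes: Sequence[str]):
    return [(g, t) for g in genes for t in expr.timepoints]


def samgs_select(
    expr: LongitudinalExpressionSet,
    collection: GeneSetCollection,
    q_cutoff: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    engine: PermutationEngine | None = None,
) -> list[str]:
    """Names of gene sets whose SAMGS q-value is <= q_cutoff.

    Each set's statistic sums squared SAM statistics over all member
    gene x time point cells; all sets share one permutation stream.
    """
    if collection.K == 0:
        raise ValueError("empty gene-set collection")
    feature_sets = {name: _all_cells(expr, members) for name, members in collection}
    results = permutation_pvalues(expr, feature_sets, B=B, seed=seed, engine=engine)
    return [r.set_name for r in results if r.q_value <= q_cutoff]


def two_level_select(
    expr: LongitudinalExpressionSet,
    collection: GeneSetCollection,
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.2,
    B: int = 1000,
    seed: int | None = None,
    engine: PermutationEngine | None = None,
) -> Signature:
    """Two-level SAMGSR: pathway screen, gene-level reduction, union of
    cores, then time-point reduction per union gene."""
    if engine is None:
        engine = PermutationEngine(expr, B=B, seed=seed)
    significant = samgs_select(expr, collection, q_cutoff, engine=engine)
    if not significant:
        warnings.warn("no gene set passed the SAMGS q-value screen; empty signature")
        return Signature([], provenance="two-level")

    union: list[str] = []
    for name in significant:
        members = collection.sets[name]
        res = reduce_set(expr, members, c_cutoff, level="gene", engine=engine)
        for g in res.core:
            if g not in union:
                union.append(g)

    entries: list[tuple[str, str]] = []
    for gene in union:
        entries.extend(_reduce_timepoints(expr, gene, c_cutoff, engine))
    return Signature(entries, provenance="two-level")


def longitudinal_select(
    expr: LongitudinalExpressionSet,
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.2,
    B: int = 1000,
    seed: int | None = None,
    engine: PermutationEngine | None = None,
) -> Signature:
    """Longitudinal SAMGSR: gene-as-set SAMGS screen, then per-gene
    time-point reduction (no pathway collection)."""
    if engine is None:
        engine = PermutationEngine(expr, B=B, seed=seed)
    feature_sets = {g: _all_cells(expr, [g]) for g in expr.genes}
    results = permutation_pvalues(expr, feature_sets, engine=engine)
    significant = [r.set_name for r in results if r.q_value <= q_cutoff]
    entries: list[tuple[str, str]] = []
    for gene in significant:
        entries.extend(_reduce_timepoints(expr, gene, c_cutoff, engine))
    if not entries:
        warnings.warn("no gene passed the SAMGS q-value screen; empty signature")
    return Signature(entries, provenance="longitudinal")


def _reduce_timepoints(
    expr: LongitudinalExpressionSet,
    gene: str,
    c_cutoff: float,
    engine: PermutationEngine,
) -> list[tuple[str, str]]:
    """Time-point-level reduction of one gene's profile (singleton t kept
    without testing)."""
    if expr.n_timepoints == 1:
        return [(gene, expr.timepoints[0])]
    cells = [(gene, t) for t in expr.timepoints]
    res = reduce_set(expr, cells, c_cutoff, level="timepoint", engine=engine)
    return list(res.core)


def per_timepoint_select(
    expr: LongitudinalExpressionSet,
    collection: GeneSetCollection,
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.2,
    B: int = 1000,
    seed: int | None = None,
) -> Signature:
    """Classical SAMGSR applied independently to each time-point slice;
    the union of per-slice core genes is tagged with its time point."""
    if collection.K == 0:
        raise ValueError("empty gene-set collection")
    entries: list[tuple[str, str]] = []
    for tp in expr.timepoints:
        sliced = expr.slice_timepoint(tp)
        engine = PermutationEngine(sliced, B=B, seed=seed)
        feature_sets = {name: _all_cells(sliced, members) for name, members in collection}
        results = permutation_pvalues(sliced, feature_sets, engine=engine)
        significant = [r.set_name for r in results if r.q_value <= q_cutoff]
        core_genes: list[str] = []
        for name in significant:
            res = reduce_set(sliced, collection.sets[name], c_cutoff, level="gene",
                             engine=engine)
            for g in res.core:
                if g not in core_genes:
                    core_genes.append(g)
        entries.extend((g, tp) for g in core_genes)
    return Signature(entries, provenance="per-timepoint")


def select(
    method: str,
    expr: LongitudinalExpressionSet,
    collection: GeneSetCollection | None = None,
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.2,
    B: int = 1000,
    seed: int | None = None,
) -> Signature:
    """Dispatch to one of the three selectors by name."""
    if method == "two-level":
        if collection is None:
            raise ValueError("two-level selection requires a gene-set collection")
        return two_level_select(expr, collection, q_cutoff, c_cutoff, B, seed)
    if method == "longitudinal":
        return longitudinal_select(expr, q_cutoff, c_cutoff, B, seed)
    if method == "per-timepoint":
        if collection is None:
            raise ValueError("per-timepoint selection requires a gene-set collection")
        return per_timepoint_select(expr, collection, q_cutoff, c_cutoff, B, seed)
    raise ValueError(f"unknown method {method!r}")
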