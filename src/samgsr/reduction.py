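"""Iterative gene-set reduction into a core subset and its residual.

Features are ordered by decreasing SAM-statistic magnitude; the set is then
partitioned into the top-k core R_k and residual complement, k = 1, 2, ...
The residual's permutation p-value c_k is computed on a frozen stream; the
chosen core size k* is the smallest k whose c_k first exceeds the cutoff
(strict inequality). If no residual loses significance the whole set is the
core. The engine is generic over the feature level: ``gene`` units carry all
of a gene's time points, ``timepoint`` units a single (gene, time) cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import LongitudinalExpressionSet
from .sam_core import PermutationEngine, SamStatMatrix

__all__ = ["ReductionResult", "order_features", "reduce_set"]


def _unit_cells(
    feature, level: str, timepoints: list[str]
) -> list[tuple[str, str]]:
    """Expand a feature unit to its (gene, timepoint) cells."""
    if level == "gene":
        return [(feature, t) for t in timepoints]
    gene, tp = feature
    return [(gene, str(tp))]


@dataclass
class ReductionResult:
    """Outcome of one reduce_set call."""

    ordered_features: list
    ck_sequence: list[float]
    k_star: int
    level: str

    @property
    def core(self) -> list:
        return self.ordered_features[: self.k_star]

    @property
    def residual(self) -> list:
        return self.ordered_features[self.k_star:]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "level": self.level,
                "ordered_features": [list(f) if isinstance(f, tuple) else f
                                     for f in self.ordered_features],
                "ck_sequence": self.ck_sequence,
                "k_star": self.k_star,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def order_features(
    sam: SamStatMatrix, features: Sequence, level: str = "gene"
) -> list:
    """Sort features by decreasing SAM-statistic magnitude (stable ties).

    ``gene`` level aggregates a gene's time points as sqrt(sum_j d_ij^2),
    matching its contribution to the SAMGS sum; ``timepoint`` level sorts
    (gene, time) cells by |d_ij|.
    """
    if len(features) == 0:
        raise ValueError("features must be non-empty")
    if level not in ("gene", "timepoint"):
        raise ValueError(f"unknown level {level!r}")
    mags = []
    for f in features:
        cells = _unit_cells(f, level, sam.timepoints)
        gi, ti = sam.cells_to_indices(cells)
        mags.append(float(np.sqrt(np.sum(sam.d[gi, ti] ** 2))))
    order = sorted(range(len(features)), key=lambda i: -mags[i])  # stable
    return [features[i] for i in order]


def reduce_set(
    expr: LongitudinalExpressionSet,
    features: Sequence,
    cutoff: float,
    B: int = 1000,
    seed: int | None = None,
    level: str = "gene",
    engine: PermutationEngine | None = None,
) -> ReductionResult:
    """Partition an ordered feature set into core and residual.

    Residual p-values c_k are evaluated on one frozen permutation stream
    (a shared :class:`PermutationEngine` may be passed in so several
    reductions use the same stream). A singleton input is returned as its
    own core without any permutation test.
    """
    if len(features) == 0:
        raise ValueError("features must be non-empty")
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in the open interval (0, 1)")
    if engine is None:
        engine = PermutationEngine(expr, B=B, seed=seed)
    ordered = order_features(engine.observed, features, level)
    S = len(ordered)
    if S == 1:
        return ReductionResult(ordered, [], 1, level)
    ck: list[float] = []
    k_star = S
    for k in range(1, S):
        residual_cells = [
            c for f in ordered[k:] for c in _unit_cells(f, level, engine.observed.timepoints)
        ]
        _, c_k = engine.set_pvalue(residual_cells)
        ck.append(c_k)
        if c_k > cutoff:
            k_star = k
            break
    return ReductionResult(ordered, ck, k_star, level)
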