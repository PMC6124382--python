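"""Time-point-specific SAM statistics, the SAMGS set statistic, and
permutation/FDR machinery.

The moderated two-class statistic for gene *i* at time point *j* is

    d_ij = (mean_diseased(ij) - mean_control(ij)) / (s(ij) + s0_j)

where ``s(ij)`` is a pooled standard deviation and ``s0_j`` a small
positive per-time-point fudge constant. The set statistic is the squared
L2 norm of the d values over all member (gene, time point) cells, and its
p-value comes from permuting subject phenotype labels (whole subjects,
all time points together) with s0_j recomputed inside each permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data_model import LongitudinalExpressionSet

__all__ = [
    "SamStatMatrix",
    "SetTestResult",
    "compute_sam_statistics",
    "fudge_factor",
    "samgs_statistic",
    "PermutationEngine",
    "permutation_pvalues",
    "qvalues",
    "write_set_results",
]


@dataclass
class SamStatMatrix:
    """SAM statistics and their components for every gene x time point."""

    d: np.ndarray        # (n_genes, n_timepoints)
    mean_d: np.ndarray   # diseased-group means
    mean_c: np.ndarray   # control-group means
    s: np.ndarray        # pooled SD per (gene, timepoint)
    s0: np.ndarray       # fudge constant per timepoint
    genes: list[str]
    timepoints: list[str]

    def cell(self, gene: str, timepoint: str) -> float:
        return float(self.d[self.genes.index(gene), self.timepoints.index(str(timepoint))])

    def cells_to_indices(self, features: Sequence[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        gi = np.array([self.genes.index(g) for g, _ in features])
        ti = np.array([self.timepoints.index(str(t)) for _, t in features])
        return gi, ti


def fudge_factor(
    s_values: np.ndarray, method: str = "median", constant: float | None = None
) -> float:
    """Fudge constant s0 for one time point, from the pooled SDs of all genes.

    ``median`` takes the median of the SDs (with a positive floor when all
    SDs vanish); ``fixed`` returns the user constant.
    """
    s_values = np.asarray(s_values, dtype=float)
    if s_values.size == 0:
        raise ValueError("s_values must be non-empty")
    if np.any(s_values < 0):
        raise ValueError("pooled SDs must be non-negative")
    if method == "fixed":
        if constant is None or constant <= 0:
            raise ValueError("method 'fixed' needs a positive constant")
        return float(constant)
    if method != "median":
        raise ValueError(f"unknown fudge method {method!r}")
    s0 = float(np.median(s_values))
    if s0 <= 0.0:
        floor = max(float(s_values.max()), 1.0) * np.finfo(float).eps
        warnings.warn("all pooled SDs are zero; fudge factor floored at eps scale")
        return floor
    return s0


def _pooled_sd(
    X: np.ndarray, y: np.ndarray, pooling: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means and pooled SD for X of shape (G, N, T), y binary per subject."""
    nd = int(y.sum())
    nc = len(y) - nd
    Xd, Xc = X[:, y == 1, :], X[:, y == 0, :]
    mean_d = Xd.mean(axis=1)
    mean_c = Xc.mean(axis=1)
    scale = 1.0 / nd + 1.0 / nc
    if pooling == "within":
        ss = ((Xd - mean_d[:, None, :]) ** 2).sum(axis=1) + (
            (Xc - mean_c[:, None, :]) ** 2
        ).sum(axis=1)
        var = scale * ss / (nd + nc - 2)
    elif pooling == "all":
        mean_all = X.mean(axis=1)
        ss = ((X - mean_all[:, None, :]) ** 2).sum(axis=1)
        var = scale * ss / (nd + nc - 1)
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")
    return mean_d, mean_c, np.sqrt(np.maximum(var, 0.0))


def compute_sam_statistics(
    expr: LongitudinalExpressionSet,
    labels: np.ndarray | None = None,
    fudge_method: str = "median",
    fudge_constant: float | None = None,
    pooling: str = "within",
) -> SamStatMatrix:
    """d_ij for every gene x time point under the given label assignment.

    ``labels`` overrides the expression set's binary outcome (used by
    permutation tests); it must be a 0/1 vector per subject with >=2
    subjects in each class.
    """
    y = expr.y if labels is None else np.asarray(labels, dtype=int)
    if y.shape != (expr.n_subjects,):
        raise ValueError("labels must align with subjects")
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("each class needs >=2 subjects (pooled SD undefined)")
    mean_d, mean_c, s = _pooled_sd(expr.values, y, pooling)
    s0 = np.array(
        [fudge_factor(s[:, j], fudge_method, fudge_constant) for j in range(expr.n_timepoints)]
    )
    d = (mean_d - mean_c) / (s + s0[None, :])
    return SamStatMatrix(d, mean_d, mean_c, s, s0, list(expr.genes), list(expr.timepoints))


def samgs_statistic(sam: SamStatMatrix, features: Sequence[tuple[str, str]]) -> float:
    """Sum of squared d over the listed (gene, time point) cells."""
    if len(features) == 0:
        raise ValueError("SAMGS statistic undefined for an empty feature set")
    gi, ti = sam.cells_to_indices(features)
    return float(np.sum(sam.d[gi, ti] ** 2))


@dataclass
class SetTestResult:
    set_name: str
    statistic: float
    p_value: float
    q_value: float | None = None


class PermutationEngine:
    """Shared permutation stream for SAMGS tests on one dataset.

    Builds the observed :class:`SamStatMatrix` plus the squared SAM
    statistics under ``B`` label permutations (or under all label
    assignments when ``exhaustive=True``). All sets and reduction steps
    evaluated against one engine share the identical stream, so their
    p-values are mutually comparable.
    """

    def __init__(
        self,
        expr: LongitudinalExpressionSet,
        B: int = 1000,
        seed: int | None = None,
        exhaustive: bool = False,
        fudge_method: str = "median",
        fudge_constant: float | None = None,
        pooling: str = "within",
    ) -> None:
        if not exhaustive and B < 1:
            raise ValueError("B must be >= 1")
        self.expr = expr
        self.exhaustive = exhaustive
        self.observed = compute_sam_statistics(
            expr, None, fudge_method, fudge_constant, pooling
        )
        y = expr.y
        N, nd = len(y), int(y.sum())
        nc = N - nd
        if exhaustive:
            assign = np.zeros((len(list(combinations(range(N), nd))), N), dtype=float)
            for b, pos in enumerate(combinations(range(N), nd)):
                assign[b, list(pos)] = 1.0
        else:
            rng = np.random.default_rng(seed)
            assign = np.empty((B, N), dtype=float)
            for b in range(B):
                assign[b] = y[rng.permutation(N)]
        self.n_perm = assign.shape[0]
        self._assign = assign  # (n_perm, N) 0/1 diseased indicators

        # Vectorized d^2 for all permutations at once via group-sum matmuls.
        G, T = expr.n_genes, expr.n_timepoints
        Xf = expr.values.transpose(0, 2, 1).reshape(G * T, N)  # (G*T, N)
        L = assign.T                                           # (N, B)
        S1 = Xf @ L
        Q1 = (Xf ** 2) @ L
        Stot = Xf.sum(axis=1, keepdims=True)
        Qtot = (Xf ** 2).sum(axis=1, keepdims=True)
        mean_d = S1 / nd
        mean_c = (Stot - S1) / nc
        scale = 1.0 / nd + 1.0 / nc
        if pooling == "within":
            ss = (Q1 - nd * mean_d ** 2) + ((Qtot - Q1) - nc * mean_c ** 2)
            var = scale * ss / (N - 2)
        elif pooling == "all":
            mean_all = Stot / N
            ss = Qtot - N * mean_all ** 2
            var = scale * np.broadcast_to(ss, S1.shape) / (N - 1)
        else:
            raise ValueError(f"unknown pooling mode {pooling!r}")
        s = np.sqrt(np.maximum(var, 0.0)).reshape(G, T, self.n_perm)
        # fudge recomputed inside each permutation
        s0 = np.median(s, axis=0)  # (T, B)
        zero = s0 <= 0.0
        if np.any(zero):
            floor = np.maximum(s.max(axis=0), 1.0) * np.finfo(float).eps
            s0 = np.where(zero, floor, s0)
        d = (mean_d - mean_c).reshape(G, T, self.n_perm) / (s + s0[None, :, :])
        self._perm_d2 = (d ** 2).transpose(2, 0, 1)  # (B, G, T)

    # -- queries ---------------------------------------------------------
    def set_statistic(self, features: Sequence[tuple[str, str]]) -> float:
        return samgs_statistic(self.observed, features)

    def set_pvalue(self, features: Sequence[tuple[str, str]]) -> tuple[float, float]:
        """Observed SAMGS statistic and its permutation p-value.

        Monte-Carlo mode uses the add-one estimator (1 + count)/(B + 1);
        exhaustive mode the exact count / n_assignments (the observed
        assignment is one of them). Ties count as >= observed.
        """
        stat = self.set_statistic(features)
        gi, ti = self.observed.cells_to_indices(features)
        perm = self._perm_d2[:, gi, ti].sum(axis=1)
        count = int(np.sum(perm >= stat - 1e-12))
        if self.exhaustive:
            return stat, count / self.n_perm
        return stat, (1 + count) / (self.n_perm + 1)


def permutation_pvalues(
    expr: LongitudinalExpressionSet,
    feature_sets: dict[str, Sequence[tuple[str, str]]],
    B: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    engine: PermutationEngine | None = None,
    **engine_kwargs,
) -> list[SetTestResult]:
    """SAMGS permutation test for several feature sets on a shared stream,
    with BH q-values computed across the tested sets."""
    for name, feats in feature_sets.items():
        if len(feats) == 0:
            raise ValueError(f"feature set {name!r} is empty")
    if engine is None:
        engine = PermutationEngine(expr, B=B, seed=seed, exhaustive=exhaustive, **engine_kwargs)
    results = []
    for name, feats in feature_sets.items():
        stat, p = engine.set_pvalue(list(feats))
        results.append(SetTestResult(name, stat, p))
    qs = qvalues([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return results


def write_set_results(results: Sequence[SetTestResult], path) -> None:
    """Write set test results as TSV: set_name, statistic, p, q."""
    import pandas as pd

    pd.DataFrame(
        [(r.set_name, r.statistic, r.p_value, r.q_value) for r in results],
        columns=["set_name", "statistic", "p", "q"],
    ).to_csv(path, sep="\t", index=False)


def qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, each in (0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    # p = 0 cannot arise from the permutation estimators but is legal input;
    # keep the contract q > 0
    return np.maximum(multipletests(p, method="fdr_bh")[1], np.finfo(float).tiny)
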