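"""Self-contained benchmark simulations.

Two designs plant causal genes inside a longitudinal two-class cohort and
label each subject through a logistic model on selected (gene, time point)
covariates:

* design 1 — gene F13A1 acts with moderate coefficients at time points 1-4
  (0.18, 0.57, 0.29, 0.41) and gene GSTM1 with a single strong coefficient
  (1.02) at time point 3;
* design 2 — gene COX4I2 at time point 1 (0.56) and gene RP9 at time
  point 5 (-0.91).

The default backbone is synthetic: per subject a multivariate normal with
AR(1) correlation across time points and exchangeable gene-gene correlation
within blocks of 20 genes, standardized per (gene, time point). A provided
expression matrix can replace it, in which case subjects are resampled with
replacement and noise genes drawn at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import GeneSetCollection, LongitudinalExpressionSet, Signature
from .sam_core import PermutationEngine
from .selectors import longitudinal_select, two_level_select

__all__ = [
    "BackboneMatrix",
    "SimulationConfig",
    "sim1_config",
    "sim2_config",
    "make_backbone",
    "block_gene_sets",
    "simulate_outcome",
    "make_replicate",
    "run_replicates",
    "ReplicateOutcome",
]

@dataclass
class BackboneMatrix:
    """Unlabeled expression matrix usable as a provided backbone."""

    values: np.ndarray  # (n_genes, n_subjects, n_timepoints)
    genes: list[str]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    @classmethod
    def from_tsv(cls, path) -> "BackboneMatrix":
        """Read a genes x subject:time matrix (no phenotype needed)."""
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        pairs = [c.split(":", 1) for c in df.columns]
        subjects = list(dict.fromkeys(s for s, _ in pairs))
        timepoints = list(dict.fromkeys(t for _, t in pairs))
        values = np.empty((df.shape[0], len(subjects), len(timepoints)))
        for si, s in enumerate(subjects):
            for ti, t in enumerate(timepoints):
                values[:, si, ti] = df[f"{s}:{t}"].to_numpy()
        return cls(values, list(df.index.astype(str)))


SIM1_TERMS = [
    ("F13A1", "t1", 0.18),
    ("F13A1", "t2", 0.57),
    ("F13A1", "t3", 0.29),
    ("F13A1", "t4", 0.41),
    ("GSTM1", "t3", 1.02),
]
SIM2_TERMS = [
    ("COX4I2", "t1", 0.56),
    ("RP9", "t5", -0.91),
]


@dataclass
class SimulationConfig:
    design: str = "custom"
    n_genes: int = 1000
    n_subjects: int = 43
    n_timepoints: int = 5
    logit_terms: list[tuple[str, str, float]] = field(default_factory=list)
    replicates: int = 50
    seed: int = 0
    rho_time: float = 0.6
    rho_gene: float = 0.3
    rho_global: float = 0.1
    block_size: int = 20
    set_size: int = 5
    backbone: str = "synthetic"
    backbone_matrix: object = None  # LongitudinalExpressionSet-like values for "provided"

    def __post_init__(self) -> None:
        self.timepoints = [f"t{j + 1}" for j in range(self.n_timepoints)]
        causal = list(dict.fromkeys(g for g, _, _ in self.logit_terms))
        n_blocks = int(np.ceil(self.n_genes / self.block_size))
        if len(causal) > n_blocks:
            raise ValueError("more causal genes than correlation blocks")
        # causal genes sit in distinct blocks (first slot of each)
        genes = [f"G{i + 1:04d}" for i in range(self.n_genes)]
        for b, g in enumerate(causal):
            genes[b * self.block_size] = g
        self.genes = genes
        self.causal_genes = causal
        for g, t, _ in self.logit_terms:
            if t not in self.timepoints:
                raise ValueError(f"logit term time point {t!r} outside the grid")


def sim1_config(**overrides) -> SimulationConfig:
    return SimulationConfig(design="sim1", logit_terms=list(SIM1_TERMS), **overrides)


def sim2_config(**overrides) -> SimulationConfig:
    return SimulationConfig(design="sim2", logit_terms=list(SIM2_TERMS), **overrides)


def _ar1_chol(t: int, rho: float) -> np.ndarray:
    idx = np.arange(t)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def _block_chol(size: int, rho: float) -> np.ndarray:
    cov = np.full((size, size), rho)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def make_backbone(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Unlabeled expression backbone of shape (n_genes, n_subjects, t).

    Synthetic mode draws each subject's genes x timepoints matrix from a
    zero-mean unit-variance Gaussian with Kronecker covariance
    (block-exchangeable genes) x (AR(1) time points), then standardizes
    each (gene, time point) across subjects. Provided mode resamples
    subjects with replacement from a user matrix and draws the non-causal
    genes at random.
    """
    G, N, T = config.n_genes, config.n_subjects, config.n_timepoints
    if config.backbone == "provided":
        src = config.backbone_matrix
        if src is None:
            raise ValueError("backbone='provided' requires backbone_matrix")
        missing = [g for g in config.causal_genes if g not in src.genes]
        if missing:
            raise ValueError(f"provided matrix lacks causal genes: {missing}")
        if src.n_timepoints < T:
            raise ValueError("provided matrix has too few time points")
        noise_pool = [g for g in src.genes if g not in config.causal_genes]
        noise = list(rng.choice(noise_pool, size=G - len(config.causal_genes),
                                replace=False))
        picked = config.causal_genes + noise
        subj_idx = rng.integers(0, src.n_subjects, size=N)
        gi = [src.gene_index(g) for g in picked]
        values = src.values[np.ix_(gi, subj_idx, range(T))].copy()
        # keep causal genes in their configured positions
        order = {g: i for i, g in enumerate(picked)}
        out = np.empty((G, N, T))
        pool_iter = iter(range(len(config.causal_genes), G))
        for gidx, g in enumerate(config.genes):
            out[gidx] = values[order[g]] if g in order else values[next(pool_iter)]
        values = out
    else:
        # Gene-gene covariance: rho_global between any two genes,
        # rho_gene within a correlation block, 1 on the diagonal; AR(1)
        # across time points throughout. Realized as a shared factor plus
        # a per-block factor plus idiosyncratic noise (all AR(1) in time),
        # mimicking the pervasive co-expression of microarray data.
        if not (0 <= config.rho_global <= config.rho_gene < 1):
            raise ValueError("need 0 <= rho_global <= rho_gene < 1")
        Lt = _ar1_chol(T, config.rho_time)
        a = np.sqrt(config.rho_global)
        b = np.sqrt(config.rho_gene - config.rho_global)
        c = np.sqrt(1.0 - config.rho_gene)
        n_blocks = int(np.ceil(G / config.block_size))
        block_of = np.arange(G) // config.block_size
        values = np.empty((G, N, T))
        for s in range(N):
            F = rng.standard_normal(T) @ Lt.T            # global factor
            Bl = rng.standard_normal((n_blocks, T)) @ Lt.T
            Z = rng.standard_normal((G, T)) @ Lt.T
            values[:, s, :] = a * F[None, :] + b * Bl[block_of] + c * Z
    # standardize per (gene, timepoint) across subjects
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def block_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Pathways nested inside the correlation blocks.

    Each correlation block is partitioned into sets of ``set_size`` genes,
    so pathway membership always respects the gene-gene correlation
    structure. Sub-block sets mimic the small effective sets produced by
    intersecting curated collections with a 1000-gene subsample.
    """
    sets = {}
    step = min(config.set_size, config.block_size)
    n_blocks = int(np.ceil(config.n_genes / config.block_size))
    k = 0
    for b in range(n_blocks):
        lo, hi = b * config.block_size, min((b + 1) * config.block_size, config.n_genes)
        for start in range(lo, hi, step):
            k += 1
            sets[f"SET_{k:04d}"] = config.genes[start:min(start + step, hi)]
    return GeneSetCollection(sets)


def linear_predictor(backbone: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Logit-scale linear predictor per subject from the configured terms."""
    gene_pos = {g: i for i, g in enumerate(config.genes)}
    tp_pos = {t: j for j, t in enumerate(config.timepoints)}
    eta = np.zeros(backbone.shape[1])
    for g, t, coef in config.logit_terms:
        eta += coef * backbone[gene_pos[g], :, tp_pos[t]]
    return eta


def simulate_outcome(
    backbone: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcome per subject, P(case) = logistic(linear predictor)."""
    eta = linear_predictor(backbone, config)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(eta)) < p).astype(int)


def make_replicate(
    config: SimulationConfig, seed: int, max_redraws: int = 20
) -> LongitudinalExpressionSet:
    """One labeled replicate; outcomes with a class of <2 subjects are
    redrawn with a sub-seed."""
    for attempt in range(max_redraws):
        rng = np.random.default_rng((seed, attempt))
        backbone = make_backbone(config, rng)
        y = simulate_outcome(backbone, config, rng)
        if y.sum() >= 2 and (len(y) - y.sum()) >= 2:
            subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
            return LongitudinalExpressionSet(
                backbone, config.genes, subjects, config.timepoints,
                {s: int(v) for s, v in zip(subjects, y)}, positive_label=1,
            )
    raise RuntimeError("could not draw a two-class outcome in 20 attempts")


@dataclass
class ReplicateOutcome:
    """Aggregated selection results over simulation replicates."""

    design: str
    methods: list[str]
    replicates: int
    signatures: dict[str, list[Signature]]
    causal_freq: dict[str, pd.DataFrame]      # method -> genes x timepoints in [0,1]
    genes_per_timepoint: dict[str, pd.Series]  # method -> mean count per timepoint
    avg_unique_genes: dict[str, float]

    def frequency_table(self, method: str) -> pd.DataFrame:
        """Percentages shaped like the benchmark tables (row 0 = mean
        gene count per time point, then % per causal gene)."""
        table = self.causal_freq[method] * 100.0
        counts = self.genes_per_timepoint[method].rename("# of genes")
        return pd.concat([counts.to_frame().T, table])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "design": self.design,
            "replicates": self.replicates,
            "avg_unique_genes": self.avg_unique_genes,
            "causal_freq": {m: df.to_dict() for m, df in self.causal_freq.items()},
            "genes_per_timepoint": {m: s.to_dict() for m, s in
                                    self.genes_per_timepoint.items()},
            "signatures": {
                m: [sig.entries for sig in sigs] for m, sigs in self.signatures.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def run_replicates(
    config: SimulationConfig,
    methods: Sequence[str] = ("two-level", "longitudinal"),
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.2,
    B: int = 1000,
    collection: GeneSetCollection | None = None,
) -> ReplicateOutcome:
    """Run the configured selectors on fresh replicates and aggregate
    causal-gene selection frequencies and signature sizes."""
    if collection is None:
        collection = block_gene_sets(config)
    signatures: dict[str, list[Signature]] = {m: [] for m in methods}
    rng = np.random.default_rng(config.seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=config.replicates)
    for r in range(config.replicates):
        expr = make_replicate(config, int(rep_seeds[r]))
        # both selectors share one permutation stream per replicate
        engine = PermutationEngine(expr, B=B, seed=int(rep_seeds[r]))
        for m in methods:
            if m == "two-level":
                sig = two_level_select(expr, collection, q_cutoff, c_cutoff, B,
                                       seed=int(rep_seeds[r]), engine=engine)
            elif m == "longitudinal":
                sig = longitudinal_select(expr, q_cutoff, c_cutoff, B,
                                          seed=int(rep_seeds[r]), engine=engine)
            else:
                raise ValueError(f"unknown method {m!r}")
            signatures[m].append(sig)
        del engine

    causal_freq, genes_per_tp, avg_unique = {}, {}, {}
    for m in methods:
        freq = pd.DataFrame(0.0, index=config.causal_genes, columns=config.timepoints)
        counts = pd.Series(0.0, index=config.timepoints)
        uniq = []
        for sig in signatures[m]:
            entries = set(sig.entries)
            for g in config.causal_genes:
                for t in config.timepoints:
                    if (g, t) in entries:
                        freq.loc[g, t] += 1
            for t in config.timepoints:
                counts[t] += len(sig.genes_at(t))
            uniq.append(sig.unique_genes)
        causal_freq[m] = freq / config.replicates
        genes_per_tp[m] = counts / config.replicates
        avg_unique[m] = float(np.mean(uniq))
    return ReplicateOutcome(
        design=config.design, methods=list(methods), replicates=config.replicates,
        signatures=signatures, causal_freq=causal_freq,
        genes_per_timepoint=genes_per_tp, avg_unique_genes=avg_unique,
    )
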