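import numpy as np
import pytest

from samgsr import GeneSetCollection, LongitudinalExpressionSet


def make_expr(values, genes=None, subjects=None, timepoints=None, y=None,
              positive_label=1):
    """Build an expression set from a (G, N, T) array and a 0/1 label vector."""
    values = np.asarray(values, dtype=float)
    G, N, T = values.shape
    genes = genes or [f"G{i}" for i in range(G)]
    subjects = subjects or [f"S{i}" for i in range(N)]
    timepoints = timepoints or [f"t{j + 1}" for j in range(T)]
    if y is None:
        y = np.r_[np.ones(N // 2, dtype=int), np.zeros(N - N // 2, dtype=int)]
    phenotype = {s: int(v) for s, v in zip(subjects, y)}
    return LongitudinalExpressionSet(values, genes, subjects, timepoints,
                                     phenotype, positive_label)


def random_expr(rng, G=6, N=8, T=3):
    return make_expr(rng.standard_normal((G, N, T)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_expr(rng):
    """6 genes x 8 subjects x 3 timepoints of pure noise."""
    return random_expr(rng)


@pytest.fixture
def constant_expr():
    """Identical expression for every subject (degenerate null)."""
    vals = np.tile(np.arange(12, dtype=float).reshape(4, 1, 3), (1, 8, 1))
    return make_expr(vals)


def planted_expr(rng, n_genes=6, n_subjects=8, n_timepoints=3,
                 signal_gene=0, signal_tps=(0,), shift=4.0):
    """Noise plus a mean shift for the positive class at chosen cells."""
    vals = rng.standard_normal((n_genes, n_subjects, n_timepoints))
    y = np.r_[np.ones(n_subjects // 2, dtype=int),
              np.zeros(n_subjects - n_subjects // 2, dtype=int)]
    for j in signal_tps:
        vals[signal_gene, y == 1, j] += shift
    return make_expr(vals, y=y)


@pytest.fixture
def two_sets():
    return GeneSetCollection({"SIG": ["G0", "G1"], "NOISE": ["G2", "G3"]})
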