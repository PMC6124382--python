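# samgsr

Pathway-guided feature selection for longitudinal two-class gene
expression studies.

The package implements the **two-level SAMGSR** algorithm — a gene set
reduction procedure applied first to genes within significant pathways and
then to time points within the retained genes — together with two
comparators (**longitudinal SAMGSR**, which treats each gene's time profile
as its own gene set, and classical **per-time-point SAMGSR**), an
SVM-based evaluation protocol (per-time-point and averaged posteriors;
error / GBS / BCM / AUPR; 5-fold CV tuning of the reduction cutoff), and a
self-contained simulation benchmark with two planted-signal designs.

## Method sketch

For gene *i* at time point *j* the moderated SAM statistic is

    d_ij = (mean_diseased(ij) − mean_control(ij)) / (s(ij) + s0_j)

with a pooled standard deviation `s(ij)` and a per-time-point fudge
constant `s0_j` (median of the pooled SDs). A gene set's SAMGS statistic is
`Σ d_ij²` over all member (gene, time point) cells; its p-value comes from
permuting subject labels (whole subjects, all time points together), and
sets are screened at a BH q-value cutoff. Reduction orders features by
|d| magnitude and keeps the smallest top-k core whose residual first loses
permutation significance (`c_k > cutoff`).

## CLI

```sh
# feature selection (expression TSV: rows = genes, columns = subject:time)
samgsr select --method two-level --expr expr.tsv --pheno pheno.tsv \
    --gmt pathways.gmt --q 0.05 --c 0.2 --perms 1000 --seed 7 --out signature.tsv

# evaluate a signature (per-time-point + averaged-posterior metrics)
samgsr evaluate --signature signature.tsv --expr train.tsv --pheno pheno.tsv \
    --test-expr test.tsv --test-pheno test_pheno.tsv --out metrics.json

# tune the reduction cutoff by 5-fold CV over 0.05..0.5
samgsr tune --method two-level --expr expr.tsv --pheno pheno.tsv \
    --gmt pathways.gmt --out tuned.json

# run a simulation design (frequency tables + per-replicate logs)
samgsr simulate --design sim1 --replicates 50 --seed 1 --out results/
```

Options can also be given in a YAML file via `--config`; explicit flags
win. Every run writes a `*.manifest.json` with all parameters, input
hashes and seeds so outputs can be reproduced bitwise.

## Python API

```python
from samgsr import (read_expression, read_gmt, align_gene_sets,
                    two_level_select, longitudinal_select, evaluate_signature)

expr = read_expression("expr.tsv", "pheno.tsv", positive_label="complicated")
sets = align_gene_sets(read_gmt("c2.gmt"), expr, min_size=2)
sig = two_level_select(expr, sets, q_cutoff=0.05, c_cutoff=0.2, B=1000, seed=7)
reports = evaluate_signature(expr, sig)
```

## Layout

| module | contents |
| --- | --- |
| `samgsr.data_model` | `LongitudinalExpressionSet`, `GeneSetCollection`, `Signature`, GMT/TSV I/O, set alignment |
| `samgsr.sam_core` | SAM statistics, fudge factor, SAMGS statistic, permutation engine, BH q-values |
| `samgsr.reduction` | feature ordering and core/residual reduction (gene and time-point levels) |
| `samgsr.selectors` | two-level / longitudinal / per-time-point selectors |
| `samgsr.evaluation` | posterior fitting, metrics, CV cutoff tuning |
| `samgsr.simulation` | synthetic backbone, the two logit designs, replicate runner |
| `samgsr.cli` | `samgsr` command-line entry point |
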