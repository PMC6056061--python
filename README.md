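# dynsub

Decomposition of signed, block-wise functional-connectivity networks into
additive subgraphs, with the downstream analyses that characterize them:

- **network construction** — window annotated regional time series into
  blocks, Pearson-correlate, split positive/negative edges into two
  non-negative channels, and assemble the edges x observations
  *configuration matrix* with its two-step normalization (per-observation
  density, per-subject edge L2).
- **subgraph learning** — regularized NMF
  `min 1/2||A - WH||_F^2 + alpha ||W||_F^2 + beta sum_t ||H(:,t)||_1^2`
  solved by alternating non-negative least squares with block principal
  pivoting (solver written in-repo, validated against `scipy.optimize.nnls`
  and an independent multiplicative-update reference), random-sampling
  cross-validated selection of `(m, beta, alpha)` over held-out subjects,
  and consensus clustering over repeated runs.
- **characterization** — relative (positive minus negative channel)
  expression summaries and rankings, paired-t/FDR contrasts across tasks
  and demand levels, edge-wise Fisher-Z contrasts, and a per-system
  core-periphery index with edge-permutation significance tests.
- **behavior** — reaction-time cost, Spearman links between expression and
  cost, and rho-weighted regional participation scores with permutation
  nulls.
- **reliability** — split-half decomposition, Hungarian matching of
  subgraph sets, and matched-pair similarity tests against the
  non-assigned-pair null.
- **synthetic cohort** — a fully seeded generator (planted rank-1 community
  subgraphs, signed per-block expression, reaction times coupled to planted
  expression) so every stage is testable without external data.

## CLI

```sh
dynsub simulate   --subjects 8 --regions 40 --planted-k 4 --seed 0 --out cohort/
dynsub optimize   --cohort cohort/ --samples 100 --folds 4 --seed 0 --out cv.tsv
dynsub decompose  --cohort cohort/ --m 4 --beta 0.3 --alpha 0.5 --runs 100 --seed 0 --out decomp.h5
dynsub characterize --decomposition decomp.h5 --partition cohort/partition.tsv --out tables/
dynsub behavior   --decomposition decomp.h5 --behavior cohort/behavior.tsv --out tables/
dynsub reliability --cohort cohort/ --m 4 --seed 0 --out reliability.tsv
```

Cohorts are plain TSV (one time-series file per subject plus annotation,
partition and behavior tables); decompositions are HDF5 containers with a
TSV export alongside.

## Library quick start

```python
from dynsub import (NMFParameters, assemble_configuration,
                    build_signed_networks, consensus_cluster,
                    normalize_configuration, relative_expression)
from dynsub.synthetic import simulate_cohort

cohort = simulate_cohort(n_subgraphs=4, seed=0)
config = normalize_configuration(
    assemble_configuration(build_signed_networks(cohort.series)))
consensus = consensus_cluster(config.weights,
                              NMFParameters(m=4, beta=0.3, alpha=0.5, seed=0),
                              R=100)
summary = relative_expression(consensus.H, config.meta)
print(summary.ranking)
```
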