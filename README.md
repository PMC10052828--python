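# isletdecon

Integrated single-cell + bulk islet transcriptomics analysis for studying
pancreatic β-cell heterogeneity. The package attributes bulk RNA-seq gene
expression to the cell types of the islet through a beta-hurdle model fit to
single-cell data, calls β-cell-specific genes, quantifies β-cell
subpopulation composition with bootstrap confidence intervals, tests gene-set
overlaps by permutation, and builds weighted co-expression networks on the
β-cell-specific portion of bulk data — including differential connectivity
between cohorts. A synthetic-data module generates datasets with the same
statistical structure and full ground truth, so every stage is testable
without downloading anything.

Intended users: computational biologists analyzing paired scRNA-seq and bulk
RNA-seq from heterogeneous tissue (islets in particular) who want cell-type
attribution rather than composition deconvolution.

## The model

Single-cell expression of gene *g* in cell type *t* is modelled as a hurdle:
an observed-zero mass plus a beta distribution on (0, 1),

```
Y ~ 0                with the observed zero fraction,
Y ~ Beta(α, β)       otherwise,
```

with a third parameter Pr(Dropout) attributing observed zeros to technical
dropout. Shapes (α, β) minimize the Kolmogorov–Smirnov distance between the
empirical CDF of the nonzero values and the beta CDF (maximum goodness of
fit); Pr(Dropout) is iterated over [0, 1], censoring that fraction of zeros
from the data side and keeping the value that minimizes the KS distance
(ties toward more dropout).

Bulk expression is approximated by the sum over cell types of expected
single-cell expression times cell count:

```
E[Y_total] ≈ Σ_t E[Y_t] · N_t ,      E[Y_t] = 1 / (1 + β/α) = α/(α+β)
```

so the relative contribution of β-cells is
`Q_β = E[Y_β]·N_β / E[Y_total]`. A gene is **β-cell-specific** when
Q_β ≥ 0.8 in every cohort.

Downstream, bulk counts restricted to specific genes are TMM-normalized,
converted to standard-normal scores per gene, correlated by biweight
midcorrelation, soft-thresholded (`|cor|^8`, chosen for scale-free topology
index > 0.9), turned into an unsigned topological overlap matrix, and
clustered into modules. Module eigengenes (first principal components) are
correlated with phenotypes (Pearson, BH FDR < 0.05). Per-gene intramodular
connectivity `k_within` compared between cohorts gives

```
kDiff = (k_A − k_B) / (k_A + k_B) ∈ [−1, 1],   |kDiff| > 0.5 ⇒ differentially connected.
```

## Worked example

```python
import numpy as np
from isletdecon import hurdle, synth

# one gene in one cell type: Beta(2, 5) expression with 30% random dropout
rng = np.random.default_rng(0)
x = rng.beta(2.0, 5.0, 2000)
x[rng.random(2000) < 0.3] = 0.0
fit = hurdle.fit_hurdle(x)
print(f"alpha={fit.alpha:.2f} beta={fit.beta_:.2f} "
      f"Pr(Dropout)={fit.pr_dropout:.2f} KS={fit.ks_distance:.3f}")
print(f"E[Y] = {hurdle.expected_value(fit):.3f}")

# full attribution on a synthetic 6-cohort, 4-cell-type dataset
specs, cohorts, truth = synth.beta_specific_scenario(n_genes=50, n_specific=10)
adata, _ = synth.generate_cells(specs, cohorts, seed=1)
tables = hurdle.fit_cohort_contributions(
    np.asarray(adata.X), adata.obs, list(adata.var_names))
calls = hurdle.call_specific_genes(tables, "beta", tau=0.8)
called = set(calls.index[calls.called])
print(f"called {len(called)} beta-cell-specific genes; "
      f"{len(called & truth)} of {len(truth)} planted genes recovered")
```

prints

```
alpha=2.05 beta=4.99 Pr(Dropout)=1.00 KS=0.012
E[Y] = 0.291
called 10 beta-cell-specific genes; 10 of 10 planted genes recovered
```

The fitted shapes recover the simulating Beta(2, 5) closely; all zeros are
attributed to dropout (a retained zero mass is unmatchable by a continuous
beta, so dropout wins whenever zeros look technical); E[Y] ≈ 2/7 is the beta
mean; and the 80%-in-every-cohort rule recovers exactly the ten genes whose
expression was planted to come ≥ 95% from β-cells.

## Command line

`isletdecon` exposes the stages as subcommands: `simulate`, `qc`,
`specific`, `markers`, `composition`, `overlap`, `phenotypes`, `network`,
and `run` (the full pipeline over a fixture directory, with a YAML config
and a reproducibility manifest). For example:

```sh
isletdecon simulate --seed 17 --out fixture/
isletdecon run --input fixture/ --out run/
```

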