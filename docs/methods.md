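# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behavior on real data.

## Quality control

Cells pass three inclusive range filters — features detected (default
500–3000), total counts (1000–30,000), percent mitochondrial counts (0–30,
identified by a configurable gene-name prefix, default `mt-`) — and then a
residual filter: an ordinary-least-squares line nFeature ~ nCount is fit on
the threshold survivors, and cells whose residual deviates more than k = 3
sample standard deviations (n−1 denominator) from the mean residual (zero by
construction under OLS) are removed. Range endpoints are inclusive because
the protocol states closed-looking ranges without openness; the residual fit
uses post-threshold cells (order: threshold filters first). Degenerate
inputs: a zero-count cell has pct-mito defined as 0; perfectly collinear
cells (zero residual SD) are all kept; fewer than three cells skips the
residual filter with a warning. Normalization is Seurat-style LogNormalize,
`ln(1 + 10^4 · count / cell_total)`, with zero-total cells mapping to zero
rows.

## Beta-hurdle attribution

Per gene × cell type × cohort, nonzero expression rescaled to the open unit
interval is fit by a beta distribution chosen to minimize the two-sided KS
distance (right-continuous empirical CDF convention). The search is an
8 × 8 log-spaced grid over shapes in [0.01, 100]² followed by Nelder–Mead
refinement in log-shape space; the returned fit is the best candidate ever
evaluated, so the reported KS is a true minimum over the search trace.
Fits need at least 20 nonzero values (low-support skip otherwise; skipped
fits contribute zero to attribution).

The rescaling `v' = v / (max · (1 + 10⁻⁶))` uses the maximum over **all** of
a cohort's cells (not per cell type), so the cell types of a gene share one
scale and the contribution ratio is scale-free. This mapping is a design
choice: log-normalized expression is unbounded, beta support is (0, 1), and
a monotone global-max rescale preserves relative contributions.

Pr(Dropout) is selected on a grid (step 0.01) over [0, 1]. Candidate d
treats a fraction d of the observed zeros as technical dropout and removes
them from the data side; the retained sample (remaining zeros, as a point
mass, plus the nonzero values) is compared against the fitted beta CDF and
the d minimizing the KS distance wins, ties broken toward larger d. Because
a continuous beta cannot absorb a retained point mass at zero, d = 1 is
optimal whenever the nonzero values alone are beta-like — which is also why
full-dropout attribution is the typical outcome on real single-cell data.
The alternative mixture reading (point mass π₀ = zero_fraction · (1 − d)
kept on the model side and compared against the full data) degenerates to
d = 0 for any zero-inflated sample and cannot reproduce the dropout-heavy
attribution this analysis relies on; the mixture CDF is still exposed
(`hurdle_cdf`) for model description, with CDF(0) = π₀.

Expected expression defaults to the plain beta mean `1/(1 + β/α)`
(equivalently α/(α+β)); a mixture-corrected variant `(1 − π₀)·α/(α+β)` is
available behind a flag and coincides with the default when all zeros are
attributed to dropout. Contributions are `term(g,t) = E[Y]·N_t` and
`Q(g,t) = term / Σ_t term` (rows sum to 1 for genes with any support; genes
with no fitted type are flagged undefined). A gene is called specific for
the target cell type when Q ≥ τ (default 0.8, inclusive) in **every**
cohort; output is sorted by min-over-cohorts Q.

The Cullen–Frey diagnostic reports squared Pearson skewness and uncorrected
kurtosis (m₄/m₂², uniform ≈ 1.8, Gaussian 3) with a bootstrap cloud and the
beta-family band (between kurt = 1 + skew² and the gamma line
3 + 1.5·skew²) for plotting.

## Markers

Marker detection uses a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction), average log fold change as the
difference of mean log-normalized values (base e; all-tied genes get p = 1),
percent-expressed per group, and Bonferroni correction with the number of
genes tested as multiplier. Cell-type markers use logFC ≥ 0.25 with ≥ 25%
of cells expressing; subtype profiles are one-vs-rest within the parent
type at logFC ≥ 0.1 and Bonferroni p < 0.01. Significance is
one-directional (the focal group must be higher-expressing), since the
profiles report overexpression.

## Composition

Subtype proportions per cohort are the observed full-cohort fractions;
uncertainty comes from drawing 1,000 cells with replacement per iteration,
100 iterations, and taking 2.5/97.5 percentile intervals (linear
interpolation between order statistics). Sampling is with replacement even
in small cohorts, keeping the procedure defined at any cohort size. Cohorts
differ significantly in a subtype when the intervals are strictly disjoint;
touching endpoints do not count. Note the nominal 95% interval is
conservative when the cohort is larger than the 1,000-cell draw (the
bootstrap spread exceeds the point estimate's sampling error), so measured
coverage sits above 95%.

## Overlap permutation test

The observed |A ∩ B| is compared against overlaps of uniform random
size-|B| subsets of the universe (default universe: all genes in the
single-cell dataset). The add-one estimator `(1 + #{null ≥ obs})/(n+1)`
avoids zero p-values. By hypergeometric symmetry, resampling A instead of B
would give the same null; the exact hypergeometric tail is provided as an
oracle and the permutation p agrees with it within Monte-Carlo error.

## Co-expression networks

Bulk counts are normalized by a TMM implementation (reference sample =
closest to the mean upper-quartile fraction; 30% M-trim and 5% A-trim;
inverse-asymptotic-variance weighted mean of M; factors normalized to
geometric mean 1; output log2 CPM on effective library sizes with a 0.5
prior). Gene-wise standard-normal conversion is the rank-based inverse
normal transform with the Blom offset ((r − 3/8)/(n + 1/4), average ranks
for ties) — read as distributional, not moment, standardization; a z-score
mode would be a one-line substitution.

Correlation is biweight midcorrelation (u = (x − median)/(9·MAD), weights
(1 − u²)² inside |u| < 1, unscaled MAD); genes with zero MAD fall back to
Pearson standardization with a warning — relevant for 4-sample cohort
subsets where the biweight degenerates. Adjacency is unsigned,
`|bicor|^power` with zero diagonal; the default power 8 reflects a
scale-free topology index above 0.9, and `pick_soft_threshold` reports the
full fit table (equal-width connectivity bins, log-log frequency
regression, sign-corrected R²). TOM is the unsigned topological overlap
`(l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)` with unit diagonal.

Modules come from average-linkage hierarchical clustering on 1 − TOM with a
**static** cut at height 0.995 and minimum module size 5; clusters below
the minimum are "unassigned". This replaces dynamic tree cutting: the cut
is deterministic, order-invariant, and sufficient for planted-partition
recovery, which is what the tests score — no claim of bit-compatibility
with any particular dendrogram-cutting heuristic is made. Eigengenes are
first principal components of the standardized module submatrix, sign-
aligned to the module mean profile and unit-variance scaled. Module–trait
relationships are Pearson correlations with Benjamini–Hochberg FDR across
all module × trait pairs, significant at q < 0.05. kME is the gene–
eigengene Pearson correlation; gene–trait correlations are emitted
alongside so membership-vs-trait scatters are reproducible.

k_within sums a gene's adjacencies (not TOM) to other genes in its module.
Differential connectivity recomputes adjacency per cohort from that
cohort's samples (same power, shared all-sample module labels) and reports
`kDiff = (k_A − k_B)/(k_A + k_B)`; genes with k_A + k_B = 0 are undefined
(flagged separately) and |kDiff| > 0.5 is strict, so kDiff = 0.5 is not
flagged. Positive kDiff means more connected in cohort A.

## Phenotypes

Duplicate assay measurements are averaged first; then insulin content =
content-tube insulin / total protein, GSIS = secretion at 11 mM glucose /
secretion at 2.8 mM, basal secretion = 2.8 mM secretion / insulin content.
Dilution factors default to 1 (measurements assumed dilution-corrected)
but can be set to the protocol's 1:5 / 1:100; GSIS is dilution-invariant
either way. Zero denominators yield NaN with a warning, never a silent
drop.

## Synthetic data: what it emulates and what it does not

The generator draws per-cell expression from the hurdle-beta laws directly
(true zeros via π₀; dropout zeros are observationally identical and only
recorded in the truth object, mirroring the real identifiability
situation), with beta variates clipped 10⁻⁶ away from {0, 1}. Cohorts carry
their own subtype mixes; subtype marker genes override the parent β-cell
law. Bulk samples are the analytic cell-count-weighted expected-value sums
scaled by mean-one lognormal noise (the noise model linking single-cell
totals to bulk is unstated upstream; lognormal-CV is this package's
choice), with exocrine contamination as a flat library share and planted
module/trait structure through shared per-sample latent signals. Phenotype
noise is Gaussian.

Default study conditions: six age × diet × sex cohorts (HF20, HM20, HF30,
HM30, LF20, LM20), four cell types (β 400, α 250, δ 150, acinar 200 cells
per cohort at scale 1 — desk-scale, far below a real experiment's tens of
thousands), four β subtypes with cohort-varying proportions
(hyperglycemic-obese males Beta1-heavy), four bulk samples per cohort.
Network tests use a separate Gaussian planted-module generator (32 samples,
equicorrelated modules, latent-linked trait) because the network stage
operates on transformed values where the Gaussian model is the natural
ground truth.

What passing tests show: the estimators recover the structure they assume,
at the stated sizes, with correct calibration of their uncertainty
statements. What they do not show: robustness to real-data features the
generator omits — UMI count noise, ambient RNA beyond a flat share,
batch effects, cell-type misassignment, non-beta-shaped expression, or
module structure that is not block-equicorrelated.

## Problem sizes and numerics

Test and acceptance runs use 2,000 cells per hurdle fit (50 genes),
~6,000-cell attribution scenarios, 100-seed bootstrap calibration, 1,000
permutations against the exact oracle, and 10–20 network seeds at 32 × 300
— sizes chosen so the full suite completes in a couple of minutes while
leaving wide margins to the pass thresholds. Numerical conventions:
right-continuous empirical CDFs; dropout ties toward 1; inclusive QC range
endpoints and inclusive τ; strict kDiff flagging; n−1 SDs in QC and
eigengene scaling; seeds propagate through `numpy.random.default_rng` so
every result is bitwise reproducible under a fixed seed.
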