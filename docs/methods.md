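# Methods

## Balances and the tree-driven ILR

A composition x = (x₁, …, x_D) lives on the simplex; only ratios of its
parts are informative.  A strictly binary rooted tree whose tips are the
D features defines a sequential binary partition.  For internal node *i*
with numerator tip set iL (the node's first child) and denominator tip
set iR, the balance is

    b_i = sqrt(r·s / (r + s)) · ln( g(x_iL) / g(x_iR) ),

with r = |iL|, s = |iR| and g the geometric mean.  Natural logarithms
are used throughout; exposing the base would only rescale every balance
by a constant and break none of the identities, so it is not
configurable.  The same coordinates arise as clr(x)·eᵀ for the basis
matrix whose row for node *i* carries a = sqrt(s/(r(r+s))) on numerator
tips and b = −sqrt(r/(s(r+s))) on denominator tips — the normalisations
that give each row unit norm and make rows of nested/disjoint nodes
orthogonal.  `build_ilr_basis` constructs this matrix explicitly;
`balances_direct` evaluates the log-ratio form node by node.  The two
routes agree to ~1e-12 and both are under test, which guards the
normalisation constants against transcription errors.

Properties that follow, all enforced by tests at 1e-9: scale invariance
(multiplying a sample by any positive constant leaves balances
unchanged, hence robustness to sequencing depth without rarefaction),
subcompositional coherence (features outside a node's clade cannot move
its balance), isometry (Euclidean distance between balance vectors
equals the Aitchison distance between compositions), and permutation
invariance (feature order is immaterial once tip labels move with it).

Orientation convention: the first child of every internal node is the
numerator.  Trees built by `upgma_from_niche` place the child cluster
with the larger mean niche first, so the root balance reads "high-niche
over low-niche"; `higher_first=False` flips the orientation globally
(all balances change sign, nothing else changes).

## Zeros

Log ratios are undefined at zero.  Count tables get a pseudocount
(default 1.0, configurable) added to *every* entry before closure; this
is the common zero-replacement and keeps the operation rank-preserving
within rows.  Proportion-valued inputs containing zeros are rejected
with a message pointing at the pseudocount, rather than silently
imputed, because a sensible replacement value depends on the (unknown)
sequencing depth.

## Mean niche, sorting, filtering

The mean niche of feature x over samples i with gradient values g_i is
ḡ_x = Σ_i g_i·x_i / Σ_i x_i.  Both sums run over samples.  By default
x_i are per-sample proportions (each sample closed first), so the
estimate is invariant to per-sample sequencing depth; `proportions=False`
weights by raw counts instead, which lets deeply sequenced samples
dominate — both variants are provided and their respective invariances
tested.  The estimate is a convex combination of sample gradient values
and therefore always lies within the observed gradient range.

`niche_sort` orders samples by gradient and features by mean niche; the
band statistic (mean absolute difference between each feature's
normalised mass-centroid row rank and its normalised column rank)
quantifies the diagonal banding that niche differentiation produces,
and is compared against a column-permutation null.

`filter_features` keeps features with study-wide totals *strictly
greater* than the threshold (defaults: 100 for survey-style data, and
the CLI accepts any value), matching the usual "more than N reads"
phrasing.

## Niche-driven UPGMA

Features are clustered by average linkage on d(x, y) = |ḡ_x − ḡ_y|, the
only natural metric on a one-dimensional niche axis.  The implementation
is a direct O(D²)-memory agglomeration rather than a call into a linkage
library because two conventions the rest of the pipeline relies on must
be deterministic: tie-breaking (among equidistant pairs, merge the pair
containing the lexicographically smallest feature identifier) and child
order (higher mean niche first).  On distinct-valued inputs the
resulting merge sets are identical to SciPy's average-linkage output,
which the test suite uses as an independent oracle.  Internal nodes are
named y0, y1, … in level order from the root, so y0 is always the root
balance.  Cophenetic heights are stored as branch lengths for reference;
balances depend only on the topology.  For 1-D UPGMA every clade spans a
contiguous interval of the sorted niche values — tested exhaustively at
small D.

## Regression on balances

`fit_ols` fits each balance against one shared design matrix (patsy
formula over the sample metadata; rank-deficient designs are rejected
with the collinear columns named).  The pooled coefficient of
determination is R² = 1 − SSE/SST with both sums taken over all
balances and samples.  Because the ILR is an isometry, SSE and SST are
invariant to the choice of tree, making this R² a property of the data
and design rather than of the tree — verified to 1e-9 across random
trees.

`fit_lme` fits a random-intercept linear mixed model per balance
(REML; Wald p-values for fixed effects).  Random intercepts only: the
grouping structure being corrected for is "subjects differ wholesale",
and random slopes would demand more levels per group than typical
designs provide.  A per-balance non-convergent fit is flagged and
reported with missing p-values instead of aborting — balances near the
tips of the tree are intrinsically volatile when features are sparse,
and one sick coordinate should not kill the analysis of the others.

Multiple testing: Bonferroni across the D−1 balances within each model
term, adjusted p = min(1, p·m), significant iff adjusted p < α.  Both
raw and adjusted p-values are always reported.

`predict_proportions` pushes fitted balances through the inverse ILR
(closure of exp(b·e)), producing predicted community compositions whose
rows sum to one.

## Synthetic data

The generators define the study conditions for every stochastic test.

*Gradient community* — unimodal responses: expected proportions ∝
exp(−(g − opt)²/2w²).  Defaults: 88 samples evenly spaced over pH
3.8–8.2 (the span of a continental soil survey), 40 taxa with optima
spread evenly across the range, breadth w = 1.0 pH unit (a realistic
niche width: taxa occupy roughly a quarter of the range), 1,000 reads
per sample (a typical rarefaction depth for survey data), and expected
proportions below 1e-4 rounded down to zero before multinomial
sampling, so generated tables contain genuine structural zeros and the
pseudocount path is exercised.

*Bloom dataset* — two groups of 50 samples, 1,000 taxa, depth 100,000.
Group 1 is uniform; in group 2 one taxon's absolute abundance is
multiplied by the bloom factor, so its expected proportion is
f/(f + D − 1) and every other taxon's is 1/(f + D − 1).  The default
factor is 100: a power calculation (proportion shift ≈ p·f/(D−1+f)
against a standard error of ≈ sqrt(2/n)·sqrt(p/depth)) shows that a
factor of order 10 shifts non-bloom proportions by well under one
standard error — no test could detect it — whereas a 100-fold bloom
(the bloomer reaching ~9% of the community, as in a real algal or
*Pseudomonas* bloom) drives per-taxon t tests into their near-total
false-positive regime while leaving bloom-free balances untouched.

*Patient gradient* — 16 subjects × 8 pH levels (5.0–8.5 in steps of
0.5), one sample per cell at depth 10,000.  Features share niche optima
across subjects but each subject carries a random subset (a feature is
present with probability 1 − idiosyncrasy, default 0.5), emulating
hosts with largely disjoint communities whose members nonetheless
respond identically to pH.  This is exactly the regime where per-taxon
tests starve for replication but balances over mean-pH clades pool the
signal.

What the generators do **not** emulate: sequencing error and chimeras,
overdispersion beyond multinomial sampling, taxon-taxon interactions,
and temporal autocorrelation.  Passing tests therefore demonstrate the
correctness and calibration of the machinery under clean compositional
sampling, not robustness to real-data artefacts.

## Numerical and scale choices

Tolerances of 1e-9 on geometric identities are loose relative to the
~1e-14 the double-precision implementations achieve.  `inverse_ilr`
subtracts the row maximum of the clr vector before exponentiating to
avoid overflow for extreme balances.  Stochastic checks use 3-sigma
Monte-Carlo bands at their stated replicate counts (e.g. family-wise
error over 500 permutation replicates; null-balance rejection over
~1,000 balances).  Test problem sizes (trees up to D = 200 for
geometry, D = 1,000 for the bloom experiment, 128-sample mixed-model
designs) were chosen as the smallest sizes at which the corresponding
regimes are unambiguous.

## Known limitations

- Only strictly binary trees are supported; polytomies must be resolved
  upstream.
- The pseudocount is a blunt zero treatment; model-based replacement is
  out of scope.
- Mixed models are random-intercept only, with Wald inference; small
  group counts make those p-values approximate.
- Mean-niche clustering is one-dimensional; multi-gradient niches are
  not modelled.
- The R² aggregation is defined for OLS only; no marginal/conditional
  R² is reported for mixed models.
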