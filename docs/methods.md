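# Methods

This note documents the statistical models, conventions and design
choices behind genecol, in the spirit of a package vignette: what is
computed, under which assumptions, and where the edges are.

## Study design and data model

The canonical design is a genecological provenance trial: `P` source
populations (default 98), each contributing `F` maternal families
(default 2), planted in `B` blocks (default 6) at each of `G` common
gardens (default 3), one plant per family per block per garden.  Plant
records carry the four design labels plus trait values; family and block
identifiers are treated as globally unique labels (a family id may not
recur under two populations).  Missing trait values are empty cells in
text I/O; sentinel numerics such as −999 are rejected rather than
silently converted, because a sentinel that slips through corrupts every
downstream mean.  Tables are written with 17-significant-digit floats and
read with round-trip parsing, so write→read is bit-exact.

Source climates are the closed set of 23 annual normals (MAP, MSP, PAS,
RH, EMT, EXT, MAT, MCMT, MWMT, TD, DD_0, DD_18, DD5, DD18, NFFD, FFP,
bFFP, eFFP, AHM, SHM, CMD, Eref, MAR).  Their declaration order is the
tie-breaking order for tree splits, which makes every fit reproducible.

## Variance components

Model (all-garden scope), every factor random:

    y = μ + garden + block(garden) + population + family(population) + ε

The per-garden variant drops the garden term.  Estimation is REML for
Gaussian traits.  For perfectly balanced complete data the REML optimum
is computed exactly through the ANOVA-stratum decomposition: the Gram
matrices of all five terms are Kronecker products of identity and
all-ones factors over the (garden, block, population, family) axes, hence
commute, and the REML deviance separates over their joint eigenspaces.
This is ~1000× faster than a generic mixed-model fit and numerically
identical to it (the test suite checks agreement with both a general
mixed-model fit and closed-form expected-mean-square estimators).
Unbalanced or incomplete data fall back to the general fit (statsmodels
MixedLM, single group, variance-component formulas).  Negative component
estimates are clamped at zero, the standard REML boundary behavior, and
proportions are components over their sum.

Counts (inflorescence number) and binary survival are modeled on the link
scale — Poisson/log and binomial/logit — via a variational-Bayes mixed
GLM, with the residual fixed by a latent-scale convention: π²/3 for
logit, ln(1 + 1/ȳ) for log with ȳ the marginal mean count.  The
variational approximation shrinks components with very few levels (the
3-level garden term) toward the prior; treat non-Gaussian garden shares
as indicative.  A `method="gaussian"` switch fits the Gaussian model to
transformed data instead (log1p for counts, identity for binary).

**Screening.**  A trait whose population-level proportion falls below
1e-5 (0.001 %) in *any* garden is dropped from *all* gardens, keeping the
trait × garden matrix balanced.

**A caution on averaging decompositions.**  The per-fit proportion of a
3-level factor is a noisy ratio whose expectation is visibly below the
true share (Jensen's inequality); when summarizing replicated designs,
average the variance components first and form proportions from the
pooled components.  The acceptance battery does exactly this.

## Trait axes

Population means per trait × garden column (named `trait@garden`,
gardens within trait) are centered and scaled, so the PCA is on the
correlation matrix and eigenvalues sum to the number of columns.  Loading
signs are fixed by flipping each vector so its largest-magnitude entry is
positive.  Axis significance uses a Monte Carlo test on cumulative
eigenvalue sums: each of B permutations (default 999, minimum 99)
shuffles values independently within every column, destroying
correlation while preserving marginals; the p-value for axis k is
`(1 + #{Σλ*_{1..k} ≥ Σλ_{1..k}}) / (B + 1)` and the reported count is the
longest unbroken prefix with p ≤ α.  At B = 199 and α = 0.05 the test is
exactly level 10/200 by construction.  On strongly structured data the
cumulative-sum statistic is liberal for trailing axes (once early axes
absorb much variance, the observed partial sums dominate the null almost
everywhere); downstream stages accept an explicit axis count when a more
conservative choice is wanted.

## Plasticity and climate screens

Plasticity of a population × trait is the sample SD (n−1) of its garden
means across gardens — the honest summary for three environments, where
slope-based reaction norms are unsupported.  Correlations with climate
are Pearson, two-sided, with Benjamini–Hochberg adjustment across the
entire response × 23-variable grid of one report; zero-variance inputs
yield missing correlations excluded from the adjustment.

The nuisance screen (collection year, greenhouse time) residualizes each
nuisance covariate on the climate set and correlates the residual with
the response (semi-partial correlation), with t-test degrees of freedom
n − 2 − rank.  Because several normals are exact linear combinations of
others (TD = MWMT − MCMT; eFFP = bFFP + FFP), the climate set is
projected onto its numerically effective column space via rank-revealing
SVD (relative tolerance 1e-10); discarding the redundant directions
changes nothing about the projection and avoids a spurious
ill-conditioning failure.  A condition-number ceiling on the retained
spectrum still rejects genuinely unstable sets.

## Multivariate regression tree (seed zones)

Responses are the **raw** PC scores of the significant axes — not
re-standardized — so each axis is implicitly weighted by the trait
variance it explains.  At each node every predictor is searched
exhaustively: numeric thresholds at midpoints of adjacent distinct sorted
values (left branch strictly less than); categorical predictors (taxon)
by all binary level-set partitions up to 12 levels, with unidentified
populations given unique levels so they segregate freely.  The split
criterion is the reduction in summed squared distance to child centroids,
computed by prefix sums; gains below 1e-12 of the response's total square
norm count as zero (round-off floor).  A split is kept iff
`gain ≥ cp × SS(root)` (default cp = 0.015) and both children hold at
least `min_node` populations (default 5).  Ties: earlier predictor in
declaration order wins, then the smaller threshold, then the earlier
enumerated level set.  These rules make refits on row-permuted data
bit-identical, and the greedy tree provably matches an independent
brute-force enumerator on small instances (tested on 50 random
instances).

**Hierarchy levels and codes.**  Splits are ordered by decreasing gain
under ancestor-closure (a split becomes eligible only after its parent),
so every prefix of the order is a valid pruned subtree; cumulative
cut-points (default 2, 7, 12) close levels 1, 2, 3, with any overflow in
one extra level.  Level-1 splits define primary zones lettered A, B, C…
in left-to-right tree order; level-2 splits refine primaries with digits;
level-3 with lowercase letters.  A zone unsplit at some level keeps its
shorter code.  Per-level explained-variance fractions are the sums of the
level's gain fractions; fractions plus residual equal 1 identically.

## Random-forest transfer functions

One regression forest per significant axis: 500 trees, ⌊p/3⌋ (≥1)
predictors drawn per split, bootstrap sampling with replacement, minimum
leaf 5 — the standard regression-forest defaults.  Fitting uses
scikit-learn; the fitted trees are flattened to plain arrays so that
serialized models (JSON with a format version) predict without
scikit-learn, bit-identically to the in-memory model.  Importance is the
per-predictor sum of node RSS decreases, averaged over trees.  Partial
dependence sweeps one predictor over 51 equally spaced points of its
observed range, averaging predictions over the training set.  Per-axis
seeds derive from the master seed and the axis index, so results do not
depend on fitting order.  Tree predictions are bounded by the training
response range; extrapolated climates saturate rather than diverge.

With strongly collinear predictors, split credit spreads across
correlated variables: single-variable importances and partial-dependence
amplitudes are diluted relative to the same signal among independent
predictors.  This is a property of the method (shared by the reference
implementations), not an artifact.

## Projection and masking

Grids are regular lon/lat rasters (WGS84 by default), rows counted from
the top-left origin, a point mapping to the containing cell.  Two
interchangeable formats: GeoTIFF (tifffile; pixel-scale/tie-point tags
plus a JSON image description with band names, nodata, CRS) and a
plain-text directory of ESRI ASCII bands with a JSON manifest, used for
version-controlled fixtures.  The extrapolation mask removes any cell
where any variable lies strictly beyond [min − k·SD, max + k·SD] of the
sampled source climates (default k = 1; boundary values survive).  Zone
rasters are int16 with a JSON legend and can be re-rendered at any
hierarchy level by code-prefix merging; trees that split on taxon are
projected once per taxon group, since overlapping taxon ranges make a
single mixed raster undefined.  Focal-point maps are per-cell Euclidean
distances in predicted PC space from a focal cell or an explicit climate
record; a masked focal point is an error that reports the nearest
unmasked cell.  Rasters are processed in fixed-order row blocks and
outputs are byte-identical for any block size.

## Synthetic studies

The generator emulates structure, not any particular dataset's numbers.
Climates arise from two latent map gradients (west–east continentality
and an elevation-like ridge field) combined linearly with noise into the
23 normals, with realistic signs (TD anti-correlated with RH, MAT driving
degree-days) and several exact identities — reproducing the collinearity
regime that stresses tree tie-breaking.  Truth carries a 3-zone latent
structure (TD threshold at its lower tercile, then the MWMT median on the
continental side), with zone centroids in standardized trait space scaled
so the minimum pairwise centroid distance is `zone_separation ×
sqrt(n_traits)` (default 2 within-zone SDs).  Per-trait variance
proportions default to values typical of such trials (garden effects
dominating; population shares of a few to ~25 %).  Plasticity enters as a
garden × population interaction whose SD grows linearly with a mildness
index (rank-scaled −TD) up to `plasticity_max_ratio` × residual SD
(default 2).  Counts are Poisson draws of an exponentiated linear
predictor; survival is Bernoulli of a logistic predictor, with latent
component variances matched to the configured link-scale proportions.
The step-response generator used in forest verification places levels ±h
with noise SD h/2, giving a signal-to-total variance ceiling of 0.8.

What the generator does **not** emulate: spatial autocorrelation of
residuals within gardens, genotype-specific mortality biasing trait
means, measurement-scale drift between gardens, and non-threshold
(gradual) adaptation surfaces.  Tests passing on these simulations show
the algorithms recover the structure they target under the declared
design; they do not certify behavior under those unmodeled features.

## Problem sizes for verification

The standing verification battery uses: 50 random instances (n = 20,
3 predictors, 2 axes) for greedy-vs-brute-force equivalence; 100 seeds of
the 98-population, 2-axis, separation-2 zone setting for recovery (pass
when ARI ≥ 0.9 at the primary level in ≥ 95 % of seeds); 50 replicates of
the full balanced design for variance-component recovery (pooled
components, MAE ≤ 0.03); 400 replicates of a 98 × 26 i.i.d. Gaussian null
at B = 199 for axis-test calibration; and 50 seeds of the ±1 step
response at 500 trees for forest recovery.  The pinned end-to-end
fixture is 12 populations × 2 families × 3 gardens × 2 blocks with a
20 × 20 four-band grid; its zone and focal rasters are golden files
compared byte-for-byte.

## Known limitations

- No cross-validation pruning, surrogate splits, or missing-predictor
  imputation in the zone tree; records missing a used predictor error.
- Categorical predictors are limited to 12 levels (exhaustive subset
  search); larger factors should be pre-grouped.
- Non-Gaussian variance components rely on a variational approximation;
  garden-level shares for count/binary traits are shrunk with only three
  gardens.
- No raster reprojection or resampling: grids must be pre-aligned with
  the analysis CRS.
- The Monte Carlo axis test's cumulative-sum prefix rule is liberal on
  strongly structured matrices (see above).
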