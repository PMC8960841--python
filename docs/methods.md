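# Methods

## Study design assumed throughout

The package targets paired long-term fertilization trials: *S* field sites,
each with unfertilized and fertilized plots (the default design is 14 sites ×
2 treatments × 4 plots = 112 samples).  Sites differ strongly in community
composition; the fertilization signal is a comparatively small within-site
contrast.  Every inferential choice below follows from that structure:
treatment tests are within-site contrasts (mixed models, restricted
permutations), while co-association is estimated *across* sites within one
treatment, where shared environmental responses express themselves as
correlated abundances.

## Occupancy filtering

OTU abundances are means over `n_reps` (default 100) rarefactions without
replacement to a common depth, with an independent RNG stream per sample.
For OTU *j*, the index of dispersion is `I_j = (σ_j²/μ_j)·O_j` with the
(n−1)-denominator sample variance and `O_j` the proportion of occupied
samples.  The test statistic `D_j = I_j·(n−1)` is compared to the upper tail
of χ² with n−1 degrees of freedom — the classical variance-to-mean dispersion
test, with occupancy entering the statistic before the comparison.  All-absent
OTUs get `I = 0` and are rare by definition.  Under a Poisson null with full
occupancy the empirical rejection rate at α = 0.05 is within ±0.02 of nominal
(asserted in tests at n = 50, 1000 OTUs).

## Zero replacement and log-ratio transforms

Zeros are replaced by their posterior expectation under a uniform Dirichlet
prior whose total strength defaults to √(sample total) ("square-root" prior;
configurable), with non-zero parts rescaled multiplicatively so ratios among
observed parts are untouched and row totals are preserved.  When the imputed
value is not below the smallest observed proportion of a sample (possible for
tables with few parts at high depth) a warning is emitted rather than an
error — the substitution is still strictly positive and multiplicative.

CLR is `ln x − mean(ln x)` per sample.  PhILR builds one balance per internal
node of a rooted binary phylogeny; the numerator is the node's *first* child
in traversal order, and the resulting basis is orthonormal in CLR space, so
Euclidean distance between samples in balance space equals the Aitchison
distance (verified to 1e−8 in tests).  No taxon or branch-length weighting is
applied: unweighted PhILR is the identifiable default, and weighting choices
would change balance values in ways the downstream tests cannot distinguish
from data.  Polytomies in input trees are resolved to a deterministic random
bifurcation (seeded shuffle + ladderization, zero-length inserted branches).

## Per-balance mixed models

Each balance is modelled as `y = β₀ + β₁·fertilized + u_site + ε` with
`u_site ~ N(0, σ_s²)`, fitted by REML.  The fit profiles the single variance
ratio λ = σ_s²/σ_e², which makes a thousand balances a few seconds' work.
The fertilization Wald F (numerator df 1) uses Satterthwaite denominator
degrees of freedom computed from the REML information of (σ_s², σ_e²); on
balanced designs this lands on the classical n − S − 1.  Kenward–Roger was
specified as first choice, but no installed library provides it, so the
documented fallback is used and recorded in the per-balance `method` field.
When the site variance hits the boundary (λ < 1e−6) the model is refitted as
fixed-intercept OLS (pooled two-sample ANOVA F) and flagged `singular`.
The family of balance p-values is corrected by Benjamini–Hochberg; balances
significant at q < 0.01 are then rank-correlated (Spearman) with the
denitrification end-product ratio.

Calibration and power are tested at the design size: the type-I error of the
F-test at α = 0.01 is within ±0.012 of nominal over 400 null fits, and
0.5-total-SD planted effects reach ≥ 80% power at q < 0.01 among 1000
balances.  The power test simulates balance matrices directly (site SD 1.5×
residual SD — sites dominate, as in real multi-site surveys); an OTU-level
log-fold effect has no fixed mapping to balance SD units, so power is a
property of the inferential procedure, not the generator.

## perMANOVA with strata

Pseudo-F from the Gower partition of squared distances
(`R² = SS_between/SS_total`), with `p = (1 + #{F* ≥ F})/(1 + n_perm)`.
Group labels are permuted only within strata (sites) when requested.  With
unbalanced site/treatment allocation, site effects masquerade as treatment
effects under free permutation: in the synthetic confounded null the free
test rejects ≳ 20% of the time at α = 0.05 while the restricted test stays
≤ 6%.  The unrestricted pseudo-F is cross-checked against scikit-bio's
permanova in tests.

## RMT threshold selection

For each candidate cutoff *t* in a grid (default 0.50–0.98, step 0.01),
entries with |r| < t are zeroed (diagonal kept), rows with no remaining
off-diagonal support are dropped, and the eigenvalue spectrum is unfolded by
a monotone cubic (PCHIP) interpolant through ~25 quantile knots of the
empirical cumulative spectral function.  Degenerate eigenvalues (within
1e−10) are merged first.  Nearest-neighbour spacings, normalized to unit
mean, are KS-tested against Exp(1); the chosen `r_T` is the smallest *t*
whose KS p exceeds 0.05, and the SSE between the spacing histogram and
`e^{−s}` is emitted per threshold for goodness-of-fit inspection.  If no
threshold passes, the scan reports "no transition" and downstream code falls
back to the top of the grid.  Matrices below 50×50 trigger a warning —
spacing statistics need eigenvalues to spare.

Thresholding is on |r| with the sign kept as an edge attribute; retained
edges additionally pass a BH-corrected correlation-test filter at q < 0.001
(at real RMT thresholds and ≥ 50 samples this drops nothing; at small n it
does real work and is logged).  Degree-zero nodes are removed.

## Topology, modules, eigengenes

Topology metrics follow the positive-edge subgraph: node/edge counts, mean
degree, global transitivity, diameter and average path length on the largest
connected component (flagged when disconnected), connectance, and a
neighbour-set Jaccard similarity averaged first over each node's neighbours
and then over nodes.  Significance uses 1000 Erdős–Rényi G(n, m) draws and a
two-tailed empirical p floored at 1/reps.

Modules are Girvan–Newman edge-betweenness communities cut at maximum
modularity (python-igraph's C implementation of the same dendrogram;
verified against clique and barbell oracles).  Modules with ≥ 5 members are
retained.  The module eigengene is the first left singular vector of the
standardized samples × members matrix (unit norm, sign oriented to correlate
positively with mean member abundance); variance explained is λ₁/Σλ — 1.0
for a perfectly correlated module, → 1/m for an m-member noise module.
Eigengenes are computed on CLR abundances by default (raw or rarefied
matrices can be passed; the choice is configurable because it is not
identifiable from first principles).

Network comparison reports common/unique edge sets keyed by unordered OTU
pair, and a per-node rewiring score: incident positive-edge |r|-weight
vectors over the union neighbourhood, normalized to unit length; `D_n` is
the mean squared distance to their centroid (0 identical, 0.5 disjoint),
plus a degree-corrected variant (÷ union-neighbourhood size).  Module
correspondence across networks uses maximum-weight bipartite Jaccard
assignment.

## Boosted-regression drivers

The estimator is pluggable (anything with fit/predict; default
scikit-learn `GradientBoostingRegressor`).  Hyperparameters are grid-searched
by K-fold CV RMSE (default grid: trees {500, 1000, 2000}, shrinkage
{0.01, 0.05, 0.1}, depth {1, 2, 3}, min leaf {5, 10}; ties break toward
fewer trees, then smaller depth).  Permutation importance shuffles one
column at a time (default 500 permutations), takes the median RMSE increase,
floors negatives at zero and rescales to percentages summing to 100; the
"top set" is predictors above 5%.  ALE curves are first-order with 10
quantile bins (duplicate quantiles merged), centred by the
observation-weighted mean.  The predictor table adds
`nosZ:nir = (nosZI + nosZII)/(nirK + nirS)` and joins diversity indices and
module eigengenes; constant columns and samples without a response are
dropped with a log entry.

## Gas kinetics and fertilization-change tests

Bottle N₂O series (six points, 0.5-h steps over 2.5 h) are fitted either
linearly or as `c(t) = c₀ + A(1 − e^{−kt})` with the rate taken as the
initial slope `A·k`; `auto` selects by small-sample AIC and non-convergent
saturating fits fall back to linear (flagged).  Rates are floored at zero.
With only six points, AIC selection is conservative: at high noise it often
prefers the linear model on mildly saturating truth, which underestimates
the initial slope — when the assay is known to saturate, fix
`model="saturating"` (the matched fit recovers the rate essentially
unbiased; verified by simulation in the acceptance report).
The end-product ratio is the rate without acetylene over the rate with
acetylene; values above 1 are flagged, a zero denominator is an error.

Percent change is computed on site means (the trial is the unit, so N equals
the number of sites) and tested with a two-sided Wilcoxon signed-rank test,
exact by full enumeration of sign assignments for n ≤ 20 (mid-ranks under
ties, zeros dropped), normal approximation beyond.  ANCOVA fits
`response ~ covariate × group` and reports the interaction F with its
degrees of freedom plus within-group standardized slopes.

## The synthetic-data generator

`generate_study` emulates the statistical structure the pipeline assumes,
with defaults fixed at the target design and not revisited:

| parameter | default | rationale |
|---|---|---|
| sites × treatments × plots | 14 × 2 × 4 | the multi-site paired design |
| frequent / rare OTUs | 600 / 3000 | log-normal SAD vs sparse low-occupancy taxa |
| planted modules | 4 (40, 40, 30, 30) | block correlation ρ_in = 0.8, ρ_out = 0 |
| site SD : residual SD | 1.5 : 1 (log scale) | sites dominate compositional variance |
| clade effect | +0.5 log units on one ~2.5–10% clade | phylogenetically clustered response |
| sequencing depth | log-normal, mean 4×10⁴ | desk-scale but realistic |
| ratio model | logit(ratio) = logit(0.35) − z(pH) + z(module B) − z(nosZ:nir) + 0.3·fert + N(0, 0.3) | known biotic/abiotic drivers; fertilization raises the ratio |

Module correlation is planted at both the site level (shared niche response
across locations) and the plot level, so across-site correlations of log
abundances approach ρ_in within modules — the signal RMT thresholding is
meant to isolate.  Counts are multinomial draws conditioned on the latent
log-normal relative abundances, preserving the compositional coupling that
CLR/PhILR assume.  The phylogeny is a Kingman coalescent over all OTUs
(binary by construction, heights scaled to 1).  Edaphic covariates and gene
abundances get site-level log-normal baselines with fertilization
multipliers (org C +10%, NO₃⁻ +50%, NH₄⁺ +30%, Ca +14%, nirK +30%,
nosZ I +20%, nosZ II +13%, nirS and pH unchanged).

What the generator does *not* emulate: taxonomy, real SAD tails, spatial or
temporal autocorrelation within sites, depth-dependent extraction biases,
interaction-driven (rather than niche-driven) co-occurrence, and measurement
error in qPCR beyond log-normal noise.  Passing recovery tests therefore
demonstrates that the pipeline recovers structure *of the kind it assumes*;
it cannot certify performance on data violating those assumptions.

## Numerical choices and degenerate inputs

Rarefaction uses per-sample `SeedSequence` spawns; a master pipeline seed
deterministically derives per-stage seeds, and identical config + seed gives
byte-identical numeric outputs.  PSD repair of planted covariances clips
negative eigenvalues at zero and renormalizes the diagonal.  Correlation
matrices exclude zero-variance OTUs; constant balances yield NA Spearman
associations (flagged); constant predictors are dropped (logged); empty
samples get zero diversity with a warning.  The REML optimizer is a bounded
scalar search on log λ with an explicit boundary comparison at λ = 0.

## Problem sizes used in tests and the acceptance script

Property tests run at 60–150 frequent OTUs and the full 112-sample design;
the null-discovery check uses 500–1000 balances; permutation-validity
contrasts use 400–1000 simulated datasets at n = 36; driver-recovery uses 20
seeds at 60 frequent OTUs with a reduced tuning grid (300 trees, shrinkage
0.1, depth 1–3).  These sizes are the package's own desk-scale choices; all
statistical conclusions they support (calibration, power, recovery) are at
the design's sample size, which is what the inference depends on.
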