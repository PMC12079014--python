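# Methods

This note documents the models, numerical choices and validation logic of
`commphylo`, in the spirit of the methods documentation of mature
statistical ecology packages. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Distance construction

**Trait distances.** Quantitative traits are standardized to zero mean and
unit variance (sample sd); categorical traits are one-hot encoded with each
indicator scaled by 1/√2, so a single-level mismatch contributes exactly 1
to the squared distance. Distances are Euclidean on the concatenated
vector, which makes the matrix Euclidean-embeddable *by construction* —
a requirement of every downstream ordination. This was preferred over
Gower's coefficient (whose square root is only conditionally Euclidean);
the encoding of categorical traits is a documented choice, since mixed
trait sets admit several defensible metrics. Sporadic missing entries are
handled by Gower-style availability weighting: the squared distance over
the traits observed in both species is rescaled by
(total traits / shared traits). Zero-variance traits are dropped with a
warning; a species with no observed traits is an error, as is a pair with
no shared observed trait. Systematically sparse traits should instead be
removed beforehand with the coverage filter (default threshold 0.80: a
trait measured for less than 80% of species is discarded), and species
whose quantitative traits could not be measured at all with the
rare-species filter (abundances of removed species are dropped, never
redistributed).

**Phylogenetic distances.** Cophenetic (patristic) distances on rooted
ultrametric trees. Ultrametricity is checked to 1e-6 relative tolerance;
empirical posterior trees failing it are accepted with a warning (dating
software emits rounding noise), synthetic trees must pass exactly.
Phylogenetic uncertainty is handled by supplying a tree set; analyses are
repeated per tree and summarized downstream (mean ± spread across trees).

**Unplaced taxa.** Species missing from the molecular trees are grafted at
random: the attachment branch is drawn uniformly among the branches of the
induced subtree of the taxonomically assigned anchor clade (the stem is
excluded when the anchor has ≥ 2 tips; a single-tip anchor means the tip's
terminal branch), the attachment depth is uniform along that branch, and
the pendant length is set so the tree stays exactly ultrametric. One
insertion draw per source tree is the default; redrawing per analysis
replicate is available by calling the routine again with a fresh RNG.

## Principal coordinates and the decoupling regression

Classical scaling of the double-centred squared-distance matrix. If any
eigenvalue is below −1e-8 (relative to the spectral scale), the Lingoes
correction is applied — a constant added to all squared off-diagonal
distances — because it is additive on squared distances, deterministic,
and preserves the ordination structure; Cailliez is deliberately not
offered. Axes with positive eigenvalues are retained; signs are fixed by
making each axis's largest-magnitude coordinate positive, so repeated runs
are bit-identical.

The decoupling step regresses all functional PCoA coordinates on a set of
phylogenetic PCoA axes by multivariate least squares. The decoupled
functional distance is the Euclidean distance among the residual
coordinates; the shared fraction jointFPdist is the explained share of
total functional coordinate variance; the phylogenetic fraction is
returned whole (preeminence to phylogeny: it may proxy conserved traits
that were never measured, so only phylogeny-independent trait variation is
isolated — no symmetric decomposition is attempted).

**Predictor-axis selection.** This is the one genuinely open design point.
An ultrametric cophenetic matrix of n species yields ~n − 1 positive axes;
regressing on all of them saturates the fit (p ≈ n predictors for n
observations) and drives the apparent shared fraction toward
p/(n − 1) ≈ 1 *even for traits generated independently of the tree* — an
artefact of overfitting, not a biological signal. The default therefore
retains the leading phylogenetic axes by the broken-stick rule, which
keeps the handful of axes encoding real tree structure (typically 1–5 for
a Yule tree) and makes jointFPdist behave as an interpretable effect size:
near 0 for independent traits, 1 for exact phylogenetic dependence, and
monotone in the simulated Brownian fraction (all three verified in the
suite). `phylo_axes="all"` (capped at n − 2 to keep residual degrees of
freedom) and explicit integers are available; requesting more than n − 2
axes is a saturation error. The residual-to-total variance ratio is
reported as a conditioning diagnostic rather than any attempt to
"stabilize" decoupled beta diversity, whose instability is a property of
the method, not something this package silently repairs.

## Alpha diversity and null models

Abundance-weighted MPD, Σ_{i≠j} a_i a_j d_ij / Σ_{i≠j} a_i a_j, and MNTD,
Σ_i a_i min_{j≠i} d_ij / Σ_i a_i, over species present at a site (a > 0
filter applied before the nearest-neighbour search, so absent pool members
are invisible). Richness-1 sites are reported as missing, never zero —
zero would fake perfect clustering. Both metrics are invariant to uniform
abundance scaling and homogeneous of degree 1 in the distances (tested).

The two null models are label permutations of the distance source — tip
names within the pool tree (random tips) or species names on the
functional distances (random traits) — with the community matrix
untouched, so observed and virtual communities have identical richness and
abundance distributions. 100 draws by default. SES uses the sample (n − 1)
standard deviation; a relative floor of 1e-12 flags degenerate
(constant-null) cases, where SES is reported as 0. The two-sided rank p is
2·min(r_low, r_high)/(n_null + 1) with the observed value included. Draws
on which a metric is undefined are excluded and counted; more than 10%
exclusions is a hard error. For tree sets, the fraction of trees with
|SES| > 1.96 and with rank p < 0.05 are both reported, since the
per-tree significance convention is a reporting choice.

Calibration is a test, not an assumption: under neutral assembly from the
pool, SES over 200 synthetic sites has mean in (−0.2, 0.2) and sd in
(0.8, 1.2) for both metrics.

## Beta diversity

All three kinds share the Sørensen-family algebra on a triple
(shared a, unique b, unique c): β_sor = (b+c)/(2a+b+c),
β_sim = min(b,c)/(a+min(b,c)), β_sne = β_sor − β_sim. Additivity holds to
1e-12 by construction and is asserted over thousands of random pairs.

*Phylogenetic*: a, b, c are branch lengths on root-to-tip paths, with
branches counted from the MRCA of the union of the two sites' species —
counting from the global root would inflate the shared component with
lineages absent from both sites. The tree used is the UPGMA
back-transformation of the phylogenetic distance fraction (average
linkage, node heights half the merge distance; exact inverse of the
cophenetic map on ultrametric inputs, verified over 100 random trees), so
the phylogenetic beta stage consumes exactly the same information as the
alpha stage; the original tree can be substituted for comparison. On a
star tree with unit branches the partition reduces to species-level
Sørensen/Simpson (oracle-tested).

*Functional*: convex-hull volumes on the first k synthetic-trait axes,
k = min(4, min richness − 1); incidence only — hull vertices carry no
abundance. Each site needs ≥ k + 1 affinely independent species;
degenerate (zero-volume) hulls are flagged and the pair dropped with a
logged reason. The intersection volume is computed exactly by intersecting
the two half-space representations, locating an interior point by the
Chebyshev-centre linear program, and taking the hull of the feasible
region's vertices; when no robustly interior point exists the volume is 0
(disjoint/touching) or, for numerically thin intersections, a seeded
Monte-Carlo rejection estimate in the joint bounding box (10⁵ points,
Laplace-smoothed standard error reported). The exact path is validated
against an independent Monte-Carlo oracle (agreement within 3 SE on
random polytope pairs in 2–4 dimensions).

Transect summaries are the mean pairwise dissimilarity of each site with
all others (n values) and the consecutive-pair series in transect order
(n − 1 values). SES of β components reuses the null machinery per pair.

## Gradient statistics

Mantel tests use Spearman correlation of the upper triangles with joint
row/column permutation of the second matrix (one-sided upper by default;
seeded; cross-checked against scikit-bio in the suite), with Bonferroni
thresholds across the campaign family. Seasonal contrasts are paired t
tests on the pairwise dissimilarity triangles (45 pairs for 10 sites,
df = 44). The SES–aridity models are OLS on centred log₁₀ aridity, its
square, season and the interactions; centring before squaring reduces the
collinearity of the linear and quadratic terms (a raw-scale option
exists). Shapiro and Breusch–Pagan diagnostics are recorded; BP p < 0.05
switches the reported standard errors to HC3 sandwich estimates with a
flag. MANOVA of component scores on aridity reports Wilks' Λ with Rao's F
approximation (Pillai available); with one component it reduces exactly to
the univariate regression F.

**IPCA / SIPCA.** The CWM matrix (variables scaled) rarely satisfies the
multivariate normality that makes PCA components independent, so the top-m
PCA loading vectors are unmixed by deflationary fixed-point ICA with the
cube (kurtosis-seeking) nonlinearity, and the data are projected on the
resulting independent loadings. The fixed-point iteration is sensitive to
its random start, so the fit restarts `n_init` times (default 5, seeded)
and keeps the unmixing whose scores have the largest total |excess
kurtosis|. Components are ordered by decreasing |excess kurtosis| and the
component count is chosen at the largest relative drop in that ordering
(ties toward fewer). The sparse variant soft-thresholds each loading
vector at its (keep_x + 1)-th largest magnitude, leaving at most `keep_x`
(default 5) nonzero traits per component, and re-projects the scores.
Season-mean CWM across years is the intended input when years do not
differ. Identifiability is verified by recovering two mixed sub-Gaussian
sources with sparse, syndrome-like mixing (few strong traits per
component, |correlation| > 0.95); with dense Gaussian-like mixing rows the
loading-space ICA objective is only weakly identified — a known property
of the method, and the reason its sparse variant suits trait syndromes.

## Synthetic gradients

The generator emulates the statistical structure of a dryland insect
survey, not its biology: a 10-site transect with aridity log-uniform over
a 3.5-fold range (so the log₁₀ transform of the models is natural), two
seasons × two years, ~60 species in two clades of a height-1 pure-birth
tree (basal split at depth 0.5), and traits
√signal·BM + √(1−signal)·N(0,1), both parts unit-variance, so `signal` is
the fraction of trait variance attributable to phylogeny; an optional
binary strategy trait thresholds a latent Brownian trait at its median.
Abundance assembly is neutral (uniform), filtering (Gaussian weight on the
focal trait, optimum moving with standardized log-aridity at
`optimum_shift` = 1 per sd, width `filter_strength` = 0.5 trait sd; the
dry season halves the width everywhere, emulating seasonal homogenization
of harsh conditions), or repulsion (sequential draws proportional to
minimum trait distance to the already-chosen set, 15 species per site).
Site totals are 50 + a log-series draw (p = 0.995), giving the strongly
uneven totals typical of such samples; the two years are independent
multinomial draws from the same expectation. Degenerate sites (richness
< 2) are resampled with a logged warning. Everything is
`numpy.random.Generator`-seeded and bit-reproducible end to end.

What the generator does *not* emulate — spatial autocorrelation, dispersal
limitation, resource dynamics, intraspecific trait variation, observation
error in trait measurement — bounds what passing tests show: they
demonstrate that the estimators recover known assembly signals under the
stated generative model, not that field data meet that model.

## Problem sizes and determinism

Default validation sizes (chosen as the smallest at which the asserted
effects are unambiguous): 20 replicate gradients (200 sites) for
calibration and scenario recovery at 100 null draws; 100 random trees for
the UPGMA oracle; 1000 random pairs per kind for additivity; ~50 polytope
pairs for hull geometry; 20 replicates per Brownian signal level. All
randomness flows through explicit seeded generators; repeated runs are
bit-identical.

## Known limitations

- Decoupled functional beta diversity inherits the documented instability
  of residual ordinations; the package surfaces diagnostics (residual
  ratio, axis counts, hull degeneracy) instead of altering the method.
- The hull intersection is exact only up to LP/Qhull tolerances; sliver
  intersections fall back to Monte-Carlo with a reported SE.
- Loading-space ICA is rotation-ambiguous for near-Gaussian data; kurtosis
  ordering and seeding make results reproducible, not unique.
- The aridity covariate is treated as an arbitrary positive index; no
  climatology is implied.
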