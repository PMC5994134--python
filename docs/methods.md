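# Methods

This note documents the statistical models behind each module, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Data model

All analyses run on four objects: a library × taxon `AbundanceTable`
(`counts` or `relative` mode; relative rows sum to 1 within 1e-9, all-zero
rows are retained but flagged), per-library `SampleMetadata` with closed
vocabularies (biotope ∈ {Fwc, Fsed, S, Msed, Mwc, Hsal, Hdv}, oxic status,
salinity, temperature class, lifestyle), a rooted branch-length phylogeny
(dendropy `Tree`), and a total taxon → (lineage, subgroup) map.  Identifiers
are opaque whitespace-free strings so they survive newick and GraphML.
Tables are TSV (comma by flag), trees newick, networks GraphML.

## Phylogenetic diversity and structure

**Faith's PD** is the branch-length sum of the minimal subtree spanning the
community's tips *including the path to the root* (rooted PD).  This
convention is stated explicitly because the alternative (unrooted, crown
only) changes single-tip and small-community values; with a rooted
convention PD of one tip is its root path, which matches summing "branch
length associated with" a set of sequences.  To compare biotopes with
unequal richness, `mean_pd_subsampled` reports the mean ± SD of PD over
seeded fixed-size subsamples (1000 by default).  The subsample size is a
required parameter — there is no natural default, and results should state
it.

**PSV** uses the shared-branch-length (Brownian) covariance matrix V with
V_ij = depth of the MRCA of tips i, j; PSV = (n·tr C − ΣC)/(n(n−1)) on the
correlation matrix C.  It is 1 on a star phylogeny and decreases with
relatedness, and is invariant to uniform branch scaling.  The null
comparison uses the *mean* PSV across sites with ≥ 2 taxa. Null model 1
shuffles each taxon's occurrences across sites (column sums preserved:
prevalence structure kept, site composition randomised); null model 2
redraws each site's taxa equiprobably from the taxon pool (row richness
preserved).  Model 2's sampler is equiprobable because only the constraint,
not the sampler, is standard.  p-values are one-sided toward clustering
(fraction of null means ≤ observed, ties counted) since clustering is the
alternative of interest; a two-sided flag exists.  Note the two models
detect different departures: restricting *which* taxa occur (one clade
only) is invisible to model 1, which permutes within the same taxon set —
the test suite exercises each model with the departure it can see.

**Unweighted UniFrac** classifies each edge by whether its subtended tips
intersect community A, B, or both; the distance is unique / (unique +
shared) branch length, 0 for identical membership, 1 for communities in
mutually exclusive lineages.

**Subgroup designation** intersects the rooted clades of two independently
inferred trees (e.g., ML and distance) and keeps maximal tip sets that are
clades in both with strictly more than `min_size` (default 10) members;
nested qualifying clades collapse to the outermost, so subgroups partition
a subset of tips and the rest are "ungrouped".  Whether "> 10" is strict is
ambiguous in common usage; strict is the default with a flag to relax.
Given a pairwise identity matrix each subgroup is annotated with its
minimum intra-group identity.  `subgroup_coverage` is the percent of
sequences inside designated subgroups, reported to one decimal.

## Ordination and permutation inference

Bray-Curtis d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j); all-zero library pairs
are undefined and flagged (set to 0).  Ordination of a Bray-Curtis matrix
is performed as principal coordinates (classical scaling of −½ J D² J):
"PCA on Bray-Curtis distances" is only meaningful as metric ordination of
the dissimilarity, and that reading is implemented.  Negative eigenvalues
are reported unmodified and excluded from variance fractions; no Cailliez
correction by default.

PERMANOVA partitions Σd²/n within/between groups; pseudo-F uses (g−1,
n−g) degrees of freedom and p = (1 + #{F_perm ≥ F_obs}) / (1 + N) — the
small-sample estimator that cannot return 0.  Environmental fits on
ordination axes use R² of a least-squares projection (numeric variables) or
1 − SS_within/SS_total about level centroids (factors), with permutation
p-values.  Rarefaction subsamples without replacement (seeded); its means
are validated against the hypergeometric closed form
Σ_i (1 − C(N−n_i, d)/C(N, d)).

## Lineage abundance distributions

Occurrence n counts libraries where a lineage is detected; mean and
variance of relative abundance (in percent) are computed **over those n
libraries only** — the occupancy-abundance plot's abundance axis refers to
libraries where the lineage was found.  Classification is occupancy-based:
core if n > 90, satellite if n < 50, intermediate otherwise (strict
inequalities; thresholds configurable, and scaled when the library count
differs from 133).

The dispersion test operationalises the variance-to-mean "index of
dispersion" as the classical Poisson dispersion test: D = s²/x̄ with test
statistic D·(n−1) ~ χ²(n−1), n supplying the degrees of freedom.  Above the
97.5 % quantile a lineage is aggregated ("non-random").  Two readings exist
for the lower tail: ecological practice treats everything at or below the
upper limit — including under-dispersed lineages below the 2.5 % line — as
"randomly dispersed", and that is the default binary call; the
`strict_two_sided` flag restricts "random" to the central 95 % interval,
which is the rule whose type-I error is calibrated (Poisson simulations
test random ~95 % of the time).  Both χ² limits are always reported, along
with the boundary curve B(n) = χ²_q(n−1)/(n−1) for occurrence-dispersion
diagrams.  Libraries with fewer than 10 total sequences are dropped before
any of this (strict "fewer than"), with a removal log.

## Co-occurrence networks and the RMT threshold

Spearman correlations are computed on mid-ranked columns over **all**
retained libraries, zeros included: joint absence/presence across libraries
is the co-occurrence signal, at the documented cost that shared
zero-inflation inflates ρ.  Taxa with total count not strictly greater than
5 are excluded first.  p-values use the two-sided large-sample t
approximation.  Edges require ρ > max(0.6, RMT threshold) and p < 0.01;
when the RMT scan selects a higher threshold it supersedes the fixed 0.6
(the interaction of the two filters is not otherwise specified; "the
stricter wins" is the conservative composition).

The RMT scan thresholds |ρ| at each grid value (default 0.30–0.95 step
0.01), drops isolated rows, and examines the nearest-neighbour spacing
distribution (NNSD) of the eigenvalues.  Unfolding fits a cubic smoothing
spline (degree configurable) to the empirical cumulative eigenvalue count
and takes spacings of the smoothed counts, normalised to unit mean;
near-degenerate eigenvalues (within 1e-8) are collapsed first, as is
customary.  Goodness of fit to the Poisson law P(s) = e^{−s} and the Wigner
surmise P(s) = (πs/2)e^{−πs²/4} is a χ² distance over 50 bins on [0, 3]
plus an overflow bin.  The selected threshold is the smallest grid value at
which Poisson fits better than GOE **and keeps doing so at every larger
evaluable threshold** — a stabilisation of "the transition can be used as a
threshold" that is robust to single-threshold noise.  Thresholds whose
spectra fall below 2 × bins eigenvalues are skipped with a warning.

Topology indices are unweighted: degree, normalised betweenness, closeness
in both conventions — the mean shortest path to reachable nodes (a farness,
the convention used when node size encodes "closeness") and its standard
reciprocal — average path length and diameter per connected component
(node-weighted mean across components for the global value), average
clustering, degree distribution, and optional average node connectivity
(O(n²) max-flow; enabled in the pipeline only for ≤ 400 nodes).  Modules
come from greedy modularity agglomeration; the algorithm is deterministic,
the seed argument is interface stability only.  Q is verified in tests
against the definitional Σ_c (e_c/m − (d_c/2m)²).

## Ancestral state reconstruction

The binary habitat trait (1 = oxic, 2 = anoxic) evolves under a 2-state
CTMC with rates q12, q21; over a branch of length t the transition matrix
has the closed form P(t) = Π + e^{−(q12+q21)t}(I − Π) with stationary rows
Π, so no numerical matrix exponential is needed.  Likelihoods use
Felsenstein pruning with per-node scaling; zero-length branches are floored
at 1e-9.  The root prior is the stationary distribution of the fitted
matrix (flat by flag) — the usual ML default when nothing else is stated.
Rates are fitted by bounded optimisation on log-rates (bounds 1e-6–1e3,
log-likelihood tolerance 1e-8; three starts for the asymmetric model, a
scalar bounded search under the equal-rates constraint, which is the
default).  Marginal node posteriors combine below-node partials with the
rest-of-tree likelihood from a preorder pass (the re-rooting formulation);
at every node the two probabilities sum to 1 and at the root they integrate
to the pruning likelihood.  Taxa get their observed state by majority oxic
status over the libraries containing them; ties break toward anoxic with a
warning (anoxic is the prevalent condition in these surveys).  Exactness is
tested against full enumeration over internal-state assignments on 3- and
4-tip trees.

## Indicators and regression trees

IndVal for lineage i and group g: specificity A = (mean abundance in g) /
(Σ over groups of group means) — rows sum to 1 — and fidelity B = fraction
of g's libraries where present; IndVal = 100·A·B.  The reported statistic
is the group maximum, with p from permuting library labels.  The MRT
recursively splits libraries on categorical metadata: level-vs-rest splits
always, all two-subset splits for variables with ≤ 5 levels; the chosen
split maximises the reduction in within-node Euclidean SS of the relative
abundance rows and must reduce it strictly.  Explicit `max_depth` (3) and
`min_leaf` (5) controls replace cross-validated size selection — CV
parameters are rarely reported and explicit controls are reproducible.  No
abundance transformation by default (Hellinger by flag).  The bookkeeping
identity root SS = Σ split reductions + Σ leaf SS is tested to 1e-10.

## The synthetic community generator

`CommunitySimSpec` defaults are the study conditions: 133 libraries with
per-biotope counts 30/32/22/19/7/11/12; biotopes imply the environment
(Fwc/Mwc oxic water columns; Fsed/Msed/Hsal/Hdv/S anoxic; salinity and
lifestyle follow the biotope), giving ~73 % anoxic libraries.  Six core
lineages occupy libraries with probability 0.8 and forty satellites with
0.2.  Where a lineage is occupied its count is at least one sequence
(zero-truncated draws): occupancy means *detection*, so realised occurrence
tracks the occupancy probability instead of being eroded by chance zeros.

Core lineage counts are negative binomial with aggregation k = 0.5 — the
dispersion test's alternative is exactly such over-dispersion — drawn
independently per member OTU (8 OTUs per lineage by default, expected
shares from a stable Dirichlet weight vector).  Drawing per OTU rather than
once per lineage keeps each lineage strongly aggregated (effective lineage
k ≈ 8·0.5) while preventing single heavy-tailed draws from collapsing
library totals, which would contaminate every other lineage's *relative*
abundance.  Satellites are zero-truncated Poisson at mean 1.0 per occupied
library, thinned multinomially to OTUs — satellites in clone-library
surveys are one-or-two-sequence detections, and their rarity is what keeps
their relative abundances inside the Poisson dispersion band even though
the denominators (library totals) fluctuate.  Mean counts are scaled by a
per-library depth factor drawn from the 100–200 range, emulating unequal
sequencing effort.  Alternate core lineages ("strict anaerobes") have their
means multiplied by 2 in anoxic libraries while the others are facultative;
applying the effect to *all* cores would largely cancel under row
normalisation and leave no compositional signal for PERMANOVA/MRT power
tests.  The effect size is configurable.

Correlated OTU pairs are planted with a Gaussian copula: latent bivariate
normals with r = 2·sin(πρ_s/6) pushed through each taxon's empirical
Poisson marginal (rate = observed column mean).  Integer ties attenuate the
realised Spearman slightly below target; with matched marginals a target of
1 yields exactly identical ranks.

Trees are pure-birth (Yule): exponential waiting times at total rate
(number of lineages)·λ, a uniformly chosen lineage splits, and a final
exponential hold makes the tree ultrametric.  Traits evolve root-to-tips
with the closed-form transition matrix; true internal states are recorded
as ground truth for ASR recovery tests.

**What the generator does not emulate:** taxonomic mis-assignment,
compositional coupling beyond the shared denominator (no SparCC-style
correlation structure), sequence-level artefacts (chimeras, primer bias),
spatial or temporal autocorrelation among libraries, and phylogenetic
signal in abundances (the simulated tree is independent of the abundance
model).  Passing recovery tests therefore demonstrates the estimators'
correctness under the stated sampling models, not robustness to those
real-data complications.

## Problem sizes and reproducibility

All stochastic procedures take explicit seeds; the pipeline spawns
per-stage seeds from one master seed via `SeedSequence`, and identical
(inputs, config, seed) give byte-identical summaries.  The test-suite and
acceptance problem sizes — 1000 dispersion simulations at 50 occupied
libraries, a 500 × 500 GOE sample, a 150-taxon planted-block matrix over
120 libraries, 500 null simulations each for PERMANOVA (n = 20, 99
permutations) and IndVal (n = 16, 99 permutations), 50 rate-recovery fits
on 300-tip trees, and the default 133-library community — were chosen so
each check has enough resolution for its tolerance (e.g., ±2 % on a 95 %
rate needs ≥ several hundred simulations) while the whole suite stays
interactive.

## Known limitations

- Spearman p-values use the t approximation, which is anti-conservative
  for very short library sets; with ≥ 30 libraries (the intended regime)
  the approximation is standard.
- The RMT scan needs ≥ 2 × bins eigenvalues per threshold; small surveys
  should lower `bins` or accept skipped thresholds.
- Only single-variable environmental fits are provided; joint multi-factor
  models on ordination axes are future work.
- `detect_modules` exposes a seed but greedy agglomeration is
  deterministic; alternative stochastic optimisers could use it.
- Under-dispersion (below the lower χ² limit) is not distinguished from
  Poisson behaviour in the default binary call; use `strict_two_sided`
  for the three-way labelling.
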