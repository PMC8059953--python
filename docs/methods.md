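# Methods

This note documents the models and procedures implemented in `morphodyn`,
the assumptions behind them, the defaults that matter, and the places where
a design choice was genuinely open.

## Scope and model overview

`morphodyn` implements the standard macroevolutionary workflow for
landmark-based ecomorphology in deep time, of the kind used to study skull
and jaw shape evolution in fossil-rich clades such as crocodylomorphs:

1. **Morphospace** — generalized Procrustes analysis (GPA) with iterative
   sliding semilandmarks, followed by PCA of the tangent-projected
   coordinates.
2. **Time-calibration** — a-posteriori dating of an input supertree
   topology against first/last appearance (FAD/LAD) occurrence ranges, with
   random polytomy resolution and stochastic tip-age draws, repeated to form
   a tree ensemble.
3. **Disparity through time** — within-bin metrics (mean pairwise distance,
   minimum-spanning-tree length, alpha-shape volume, Foote partial
   disparity) with bootstrap confidence intervals and partial rarefaction,
   and phylogenetic time-slicing with Brownian ancestral state estimates.
4. **Evolutionary tempo** — a multivariate variable-rates Brownian model
   with reversible-jump MCMC over branch/clade rate shifts, stepping-stone
   marginal likelihoods, and Bayes-factor model comparison.

All stages are exercised end to end on synthetic data with known ground
truth; the generator is first-class, tested code.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, not
the anatomy of any real clade.

* **Tree.** Forward birth–death simulation conditioned on a total tip count
  (extinct + extant), because fossil supertrees are dominated by extinct
  tips. Defaults: 64 tips, birth 0.07 / death 0.04 per Myr, i.e. net
  diversification 0.03 per Myr and a substantial extinct fraction; root
  ages land around 10²  Myr, comparable to a long-lived fossil clade. The
  present is set one waiting time after the size condition is met so every
  pendant branch has positive duration.
* **Rate regimes.** Shifts are planted on clades (stem branch included) and
  compose multiplicatively when nested; unshifted branches carry scalar 1.
  Recovery studies plant one clade covering 20–40% of tips at scalar 10.
* **Traits.** Independent Brownian motion per trait; an increment along a
  branch of duration *t* with scalar *r* has variance σ²·r·t. Default base
  variance 10⁻³ per Myr, which over a ~10² Myr tree yields score standard
  deviations of order 0.1–0.5 — the scale of empirical morphospace axes.
* **Landmarks.** Trait vectors are mapped to 2D configurations as
  `mean_shape + Σ score_j · basis_j`, where the deformation basis is built
  by orthonormalising random fields against the 4-dimensional similarity
  subspace (two translations, rotation, scaling) at the mean shape. This
  guarantees the scores act isometrically in Kendall tangent space, so GPA +
  PCA provably recovers their pairwise geometry. Each configuration is then
  disturbed by a random rotation, translation, and log-uniform [0.5, 2]
  scaling — exactly the nuisances GPA must remove.
* **Occurrences.** LAD equals the true tip age; FAD extends it by
  Uniform(0, min(5 Myr, pendant branch duration)). The 5 Myr cap is of the
  order of stage-level dating uncertainty. Real occurrence data have
  structured, non-uniform range errors; this model is deliberately simple
  and is a stand-in, not a reconstruction of any published dataset.

What passing tests on these worlds show: the pipeline inverts its own
generative assumptions (Brownian motion, multiplicative clade shifts,
uniform range errors). What they do not show: robustness to model
violations in real data — correlated traits, preservation biases,
non-Brownian evolution.

## Morphometrics

GPA iterates {center, scale to unit centroid size, rotate onto the current
consensus, re-average}. Reflections are excluded in the rotation solver
(determinant forced positive): 2D outlines have a biological left/right
identity. Convergence is declared when the consensus' summed squared
displacement falls below `tol` (default 10⁻⁹, max 100 iterations).

**Sliding.** Semilandmarks slide along the chord between their flanking
points. The default criterion minimises the thin-plate-spline bending
energy of the deformation from the current consensus (a linear solve per
specimen per iteration, with a 10⁻¹² ridge); a Procrustes-distance
criterion (orthogonal projection of the residual onto the tangent) is
available as `slide_criterion="procrustes"`. Sliding admits a soft mode —
collective tangential drift that changes the consensus without reducing
misfit — so the iteration also stops when the consensus change plateaus
(change shrinking by < 2% per round after iteration 3). Whether sliding
should target the grand consensus each iteration is not standardised across
packages; this implementation re-slides against the updated consensus every
round.

**PCA.** Aligned configurations are orthogonally projected onto the tangent
space at the consensus, then eigen-decomposed about their mean. Axis signs
are fixed by making the largest-magnitude loading positive. Score distances
equal Procrustes distances exactly up to tangent-projection curvature,
which is O(s³) for shape deviations of size *s*; the isometry tests
therefore use small deformations (scores ~3·10⁻⁴), the regime where a
10⁻⁶-relative round-trip tolerance is meaningful.

**Axis selection.** Broken-stick with strict inequality (retain axis *i*
while its observed variance share exceeds (1/p)·Σ_{m≥i} 1/m, stopping at
the first failure). The pipeline accepts an explicit axis-count override,
since empirical studies often fix the count a priori.

## Time-calibration

Ages are Ma before present (larger = older); durations are Myr; bins are
half-open [older, younger).

* **Polytomy resolution** builds a uniformly random binary resolution of
  each multifurcation by sequential attachment of child subtrees at
  uniformly chosen edges (stem included) — this gives the exact uniform
  distribution over rooted binary topologies.
* **Tip ages** are drawn Uniform[LAD, FAD] per taxon; tips are placed at
  the sampled point, not at LAD.
* **equal** initialises node ages at the oldest descendant tip age, extends
  the root by `root_extension` (default 10 Myr — the outgroup-based root
  constraint of empirical studies is dataset-specific, so this is exposed
  as configuration), then lets every zero-length branch absorb time by
  sharing the span down from the nearest strictly older node equally along
  the intervening chain, processed root-to-tips.
* **mbl** pushes ancestors older, tips rootward, so every branch is at
  least `min_branch`.
* **cal3-style** dating draws each node age older than both its children
  and its oldest descendant FAD by an Exponential(p − q + r) waiting time
  (rejected unless positive). This is the package's own construction in the
  spirit of sampling-rate-calibrated dating: branching (p) and sampling (r)
  rates shorten unobserved history and extinction (q) lengthens it, so node
  ages collapse toward the observed record as sampling improves. It is not
  a reimplementation of the original three-rate algorithm; the defaults
  (0.1, 0.1, 0.5 per Myr) are placeholders and should be set from data.
* **Ensembles** (default 100 trees) derive per-tree seeds from
  (seed, index) via `numpy` seed sequences, so tree *i* is reproducible in
  isolation.

## Disparity

* MPD and MST use all supplied morphospace axes; alpha-shape volumes use
  exactly the first three. Alpha is a circumradius threshold: Delaunay
  tetrahedra with circumradius ≤ alpha contribute their volume, and
  alpha = ∞ equals the convex hull. Degenerate (coplanar) inputs give
  volume 0 with a logged warning; sparse samples (n < 2, or < 4 for
  volumes) give NaN, never zero.
* Foote partial disparities PD_g = Σ_{i∈g} ‖x_i − x̄‖²/(N−1) sum exactly to
  the total variance-style disparity.
* Bootstrap CIs are percentile intervals over resamples with replacement
  (default 1000 iterations, 95%); percentile intervals slightly undercover
  for MPD at small n, which the coverage test quantifies at n = 100.
* Partial rarefaction: bins above the mean within-bin sample size (taken
  over non-empty bins, rounded to the nearest integer) are subsampled to
  it; smaller bins keep their full sample.
* Bin membership: a taxon joins every bin its [FAD, LAD] range overlaps;
  bins are closed on the older bound and open on the younger, so boundary
  ties resolve deterministically.
* Ancestral states are joint maximum-likelihood Brownian estimates (the
  minimiser of Σ (Δx)²/t with tips fixed), solved exactly as a sparse
  weighted-Laplacian system per trait.
* Time-slicing collects one value per branch crossing the slice age.
  `gradual` (default) interpolates linearly along the branch — the Brownian
  conditional expectation given the endpoints; `punctuated-parent` /
  `punctuated-child` take the older / younger endpoint. Distances are
  computed in score space, which matches Procrustes distances under a
  full-rank ordination.

## Variable-rates model

Traits are treated as independent after ordination (diagonal trait
covariance), consistent with feeding PC scores to the model. The
phylogenetic likelihood is computed by the pruning (independent-contrasts)
recursion, JIT-compiled with numba; a dense multivariate-normal oracle
checks it to < 10⁻⁸ in the tests.

**Parameterisation and priors.**

* Shifts live on single branches or whole clades (stem included); the
  effective scalar of a branch is the product of the shifts covering it.
* Shift count: uniform on {0, …, max_shifts}, default max = branches/2.
  Location sets are uniform over subsets of the branch+clade location pool.
* log scalar ~ Normal(0, 1.2²).
* σ²_j ~ InverseGamma(a₀ = 2, b₀), with b₀ defaulting to the
  homogeneous-model REML variance estimate so the prior mean sits at the
  empirical scale. A proper prior is required for marginal likelihoods; the
  same prior is used in both compared models, so Bayes factors are
  comparable. Both hyperparameters are configurable and recorded.
* The root is handled by REML (contrast likelihood, root marginalised) by
  default, removing p nuisance parameters; `root_mode="ml"` adds explicit
  root states under a proper Normal(0, 10²) prior with conjugate updates.

**Moves.** Add a shift at a uniformly chosen unoccupied location (branch or
clade scope with equal probability; the new scalar is drawn from its
prior), delete a uniformly chosen shift, multiplicatively perturb a scalar
(log-scale random walk, step 0.35), and a conjugate Gibbs draw of σ²
(tempered appropriately inside stepping-stone stones). The
reversible-jump acceptance ratios account for the kind-specific proposal
masses; with the likelihood forced flat the chain reproduces its prior,
which the sampler-validity test checks by chi-square on 10⁴ thinned
shift-count samples.

**Chain sizes.** Desk-scale defaults are 200 000 iterations, 20% burn-in,
thinning 100, and K = 20 stones × 2 000 iterations for stepping-stone —
sizes chosen so a full recovery study (20 replicates of 64-tip worlds,
three chains each) completes in minutes on one CPU while leaving effective
sample sizes in the hundreds. Production-scale values (the billions of
iterations and 1000-stone ladders used in empirical studies) are accepted
through the same configuration fields.

**Stepping stone.** Power ladder β_k = (k/K)^(1/0.3), likelihood tempered,
prior untempered; the log marginal likelihood sums log-mean-exp likelihood
ratios between adjacent stones, with chain state carried stone to stone
(25% per-stone burn-in). The homogeneous model runs the same machinery with
the shift dimension fixed at zero. Bayes factors are reported as
2·Δlog-marginal-likelihood, with > 10 read as very strong support.

**Summaries.** The consensus rate tree is majority-rule over clade
bipartitions, with each branch carrying the mean posterior-mean scalar over
the trees containing that clade. Rates through time average branch scalars
per time bin weighted by the branch duration inside the bin; because that
average is linear in the scalars, averaging over posterior samples equals
using posterior-mean scalars, which is what the implementation does. An
unweighted per-lineage variant (branches crossing the bin midpoint) is
available behind `variant="lineage"`; which weighting best accounts for
shared ancestry is a genuinely open choice and both are reported as such.

## Numerical details and edge cases

* Zero-centroid-size configurations, inconsistent landmark counts, missing
  occurrence rows, non-binary topologies at dating time, and unknown
  metric/model names are rejected with the offending item named.
* The bending-energy matrix uses a pseudo-inverse; a 10⁻¹² ridge stabilises
  the sliding solve.
* MST uses the sparse-graph algorithm on a +1-offset distance matrix so
  duplicate points (legal, zero-length edges) are not dropped; the offset
  cancels exactly.
* Dated-tree invariants (strictly positive durations, tip ages within
  occurrence ranges) are asserted after every dating call.
* ESS uses the initial-positive-sequence truncation; a constant series
  reports n with a warning, and strongly antithetic series may legitimately
  exceed n.
* All stochastic stages derive independent substreams from one seed via
  `numpy.random.SeedSequence`; pipeline reruns are bit-identical, which the
  manifest's SHA-256 checksums make checkable.

## Known limitations

* Traits are modelled as uncorrelated after ordination; there is no
  non-diagonal multivariate model.
* The cal3-style dating is a simplified waiting-time construction (see
  above), and the `equal` root constraint is a flat extension rather than
  an outgroup-age prior; Bayesian tip-dating methods are out of scope.
* Only 2D landmarks are supported; no thin-plate-spline deformation-grid
  rendering, and no Auer–Gervini axis estimator (broken stick plus an
  explicit override covers axis selection).
* Sampling-standardisation of disparity is limited to bootstrap and the
  partial-rarefaction rule; no shareholder-quorum or coverage-based
  subsampling.
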