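# Methods

This note records the models implemented in `modulevo`, their assumptions,
the defaults and why they were chosen, and the places where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Shape model and Procrustes pipeline

Specimens are k×3 landmark configurations with a fixed landmark order.
Semilandmarks are resampled equidistantly in arc length along their polyline
curve (`morpho.resample_curve`) and **thereafter treated as fixed points**:
no bending-energy or minimum-Procrustes-distance sliding is performed.  This
keeps alignment a pure similarity-group quotient and makes the equidistant
arraying itself the semilandmark treatment.  Users who need slid
semilandmarks should slide upstream and feed the result in.

GPA centers each configuration, scales it to unit centroid size (full
Procrustes), and iterates optimal rotations against the evolving consensus.
Rotations come from the SVD solution with the determinant forced to +1, so
reflections are never introduced.  Convergence is declared when the
consensus moves by less than 1e-10 (Frobenius norm), with a cap of 100
iterations; typical datasets converge in well under ten.

Allometry is removed by multivariate linear regression of the flattened
aligned coordinates on centroid size.  Raw size is the default regressor
(log size is a switch) because the shape displacement of interest is linear
in the size measure that GPA removed; with the narrow size ranges typical of
intraspecific samples the two choices are nearly collinear anyway.
r² = SS_model/SS_total over all coordinates; the permutation p-value
shuffles the size vector and uses the (b+1)/(m+1) convention, so p ∈ (0, 1].
The residual dataset is residuals + consensus, and residualizing twice is a
no-op (this idempotence is tested).

Workflow order for phylogenetic ("natural") data: GPA → allometry residuals
→ OTU means → PCA and EMMLi.  The disparity analysis additionally supports
the variant that keeps the allometric component in the shapes and instead
puts centroid size into the phylogenetic regression as a covariate — both
conventions are in active use and they answer slightly different questions.

## EMMLi: likelihood modularity model selection

Each landmark is one trait.  The correlation between landmarks i and j is
the absolute congruence coefficient of their per-observation 3-vectors,
|Σ_s⟨u_is, u_js⟩| / sqrt(Σ_s‖u_is‖² Σ_s‖u_js‖²) — a single number per pair
rather than one per coordinate axis.  Observations are either mean-centered
specimen deviations or phylogenetic contrasts (contrasts are mean-zero by
construction); n_obs must exceed 3 because the Fisher-z variance is
1/(n_obs − 3).

A model = partition × pooling mode.  Pools: m within-module pools under
`sep` (1 under `same`), m(m−1)/2 between-module pools under `sep` (1 under
`same`); a one-module partition yields only the single-ρ null.  Each pool's
ρ̂ maximizes the Gaussian likelihood of the Fisher-z correlations on the
grid {0, 0.01, …, 0.99}; sufficient statistics (Σz, Σz², n per pool) make
the grid maximization exact and O(pools × grid).  K = #pools + 1 and
AICc = −2 logL + 2K + 2K(K+1)/(n_c − K − 1) with n_c = k(k−1)/2.  The +1 in
K follows the EMMLi framework's parameter-count convention.  "Model likelihood" is exp(−ΔAICc/2) and the posterior probability
the Akaike weight.  AICc ties break toward the smaller K.  Models whose K
approaches n_c are flagged unfittable and excluded with a warning.  A
Brent refinement around the best grid point exists but is off by default so
repeated runs are bit-identical.

Phylogeny: correlations are computed from independent contrasts of the OTU
mean shapes, once per tree of the posterior-like sample, with
n_obs = n_tips − 1.  Aggregation reports best-model selection frequencies,
runs with competitors within 2 AICc of the winner (the conventional
reporting threshold), and per-pool ρ̂ distributions.  Whether the original
analyses set the Fisher-z n to contrast counts or specimen counts is not
documented anywhere we could check; contrasts are the coherent choice for
tree-corrected matrices and are the default, with specimen counts available
for non-phylogenetic (experimental) data.

Shipped example partitions (mandible: six modules named tooth-bearing,
lateral-line canal, quadrate-articular joint, articular excurvation,
ascending arm, retro-articular over 109 landmarks; pharyngeal jaw: five
modules over 45 landmarks) use contiguous landmark blocks.  They carry the
right module counts and naming for the feeding-bone application but are
illustrative — digitization-scheme-specific assignments should be supplied
as partition files.

Note that ρ̂ from real or realistically simulated pipelines is attenuated
relative to the generating correlation: measurement noise, Procrustes
alignment, and contrast standardization all shrink observed correlations.
Recovery tests therefore compare within- versus between-module ρ̂ and
model ranking, not ρ̂ against its generating value.

## Trees, contrasts, and the Mk model

Trees are consumed, never inferred; dendropy handles Newick/NEXUS I/O and
pruning (degree-2 nodes are suppressed with branch lengths summed).
Supplied trees must be ultrametric where an operation requires it; a
proportional depth-rescaler is available only behind `approximate=True`
because proper rate-smoothed dating is out of scope.

Independent contrasts follow the standard pruning recursion with
branch-length extension of ancestral values; trees must be strictly
bifurcating (the generator only produces such trees).  The phylogenetic
covariance C is the shared-path-length matrix; GLS means and C^(−1/2) come
from dense algebra, which is appropriate at these tree sizes (tens of
tips).

The habitat character is a two-state continuous-time Markov model with
states indexed (shallow, deep).  The pruning likelihood uses the closed-form
2×2 transition probabilities.  Defaults: ER structure (one rate), root prior
= stationary distribution of the fitted rates; ARD and equal/fixed priors
are switches.  ER is the common default for binary ecological characters
and the single rate is much better identified at small tip counts; the
directional asymmetry question can be asked with ARD when the data can
support it.  Rates are optimized on log scale within [1e-8, 1e3];
monomorphic tip states drive the estimate to the lower bound, which is
reported with a warning, not an error.

Stochastic character maps draw node states from their joint conditional
distribution (backward sampling on the pruning partials) and fill branches
with endpoint-conditioned CTMC paths: rejection sampling capped at 1000
attempts, then a uniformization sampler, guaranteeing termination at any
rate.  One map per tree is the default, matching the one-map-per-
posterior-tree design; the count is configurable.

**Saturation caveat.**  Mapped transition counts inherit the variance of
the ML rate estimate, and the map count is convex in the rate, so averages
over replicates are biased upward when the character is saturated relative
to the tip sample (e.g., ~11 expected transitions on a 22-tip tree).  This
is a property of the standard ML-SIMMAP toolchain, not of this
implementation — cross-checking this package against an independent
reference implementation on identical data gives matching per-dataset
counts.  The transition-count recovery test therefore runs at the scale of
a full habitat sample (90 tips at the same expected number of transitions),
where the rate is well identified and mapped counts recover the simulated
truth closely; transition counts estimated from few tips should be read as
upper-tail-heavy.

## Rates, disparity, MANOVA

σ²_mult of a group is the mean squared phylogenetically whitened deviation
per trait: residuals from the GLS ancestral mean, premultiplied by C^(−1/2),
squared, summed over the group, divided by (n_g × p).  Module rates use the
same transform restricted to the module's coordinate columns; sums of
squares are additive, so the p_m-weighted module rates recombine exactly to
the whole-shape rate (tested to 1e-9).

Significance of the **between-group** rate ratio comes from permuting group
labels across the whitened residual rows.  Under the common-rate null those
rows are independent and identically distributed, so the permutation test
is exactly calibrated at any trait dimension — a property a parametric
bootstrap with a covariance matrix estimated from n ≪ p observations cannot
deliver (its simulated ratio distribution is over-dispersed and the test
becomes severely conservative; this drove the design choice).  The
**among-module** test cannot permute (traits are not exchangeable across
modules), so it keeps the parametric bootstrap: tips are simulated under a
single common rate with every trait variance equalized to the pooled rate
while preserving the observed among-trait correlation structure, which is
what keeps the pairwise module tests near nominal size.  Both tests use the
(b+1)/(m+1) convention.

σ² uncertainty intervals, when a tree sample is supplied, are the 2.5/97.5
percentiles of the per-tree estimates across the ensemble.  How such
intervals "should" be built is genuinely open (ensemble percentiles versus
simulation quantiles); the ensemble-percentile choice mirrors the
per-posterior-tree analysis design and is labeled in the output
(`RateResult.interval_method`).

Disparity is Procrustes variance with denominator n (the convention of the
applied morphometrics toolchain; `ddof=1` is a switch), compared between
groups by |ΔPV| under label permutation.  The phylogenetic variant computes
PV on residuals of a GLS regression of shape on centroid size under
covariance C.

The MANOVA computes Wilks' Λ = det(W)/det(T) and Rao's F approximation.
The phylogenetic version keeps the observed F but simulates its null from
multivariate Brownian motion with the evolutionary rate matrix estimated
from contrasts of the observed scores (a residual-based estimate; whether
to estimate from raw scores instead is underdetermined, and the two differ
only through the GLS mean).  Five PC score columns is the default input
dimension.  The ordinary version uses the F distribution (or residual
permutation).

## Synthetic data: what it emulates, what it does not

The generator's defaults encode the study conditions the pipeline targets:
22 OTUs in two habitat classes, 3 individuals per OTU, a 1000-tree
posterior-like ensemble, a binary habitat character with approximately 11
expected transition events on the default tree, and a 109-landmark
configuration (14 fixed + 95 semilandmarks on curves) in six modules
(25/18/15/17/20/14 landmarks).

* **Trees**: pure-birth (Yule) conditioned on the tip count, rescaled to
  depth 1.  The comparative methods consume only the covariance C, so a
  richer diversification model would add nothing the analyses can see.
  Posterior uncertainty is emulated by mean-one lognormal branch-length
  jitter (sd 0.1 by default) followed by proportional re-ultrametricization
  to the original depth; topology is held fixed (how the original posterior
  varied — topology versus lengths — is not documented, and branch-length
  jitter is the minimal choice that makes per-tree analyses non-degenerate).
* **Habitat**: symmetric Mk rates (1.35, 1.35) per unit depth; at the
  default tree shape (mean total length ≈ 8) this yields ≈ 11 expected
  transition events, with the root drawn from the stationary distribution.
* **Shapes**: a landmark-level correlation matrix R with rho_within = 0.7
  in the diagonal blocks and rho_between = 0.2 elsewhere (checked positive
  definite before Cholesky); OTU mean displacements are matrix-normal with
  covariance σ²·(C ⊗ R), drawn independently and identically for each of
  the three coordinate axes — the "one number per landmark pair"
  representation that the congruence-coefficient matrix consumes.
  σ² = 1e-4 puts per-coordinate BM standard deviations at 1% of the unit
  centroid size, the order of magnitude of shape variation in these bones.
  Individuals add isotropic noise (sd 0.002) and an allometric displacement
  along one fixed unit shape vector, slope 0.15 per unit log-size deviation
  (log-size sd 0.1); with OTU-clustered shapes this produces shape-on-size
  r² values of the same order as reported for real feeding bones
  (≈ 0.05–0.2, dominated by the clustering, not the slope).
* **Template**: fixed landmarks on a closed 3D outline with semilandmarks
  on slightly bowed polylines between them — smooth enough to exercise the
  curve resampler, with no pretense of anatomical realism.

What passing tests on these data do **not** show: robustness to
digitization error structure (noise here is isotropic and independent),
missing landmarks (not modeled), sliding-semilandmark effects, topology
uncertainty in the tree ensemble, or non-Brownian evolution (no OU or
early-burst regimes).  Results on real data inherit those caveats.

## Numerical choices and degenerate inputs

* Every stochastic routine takes a seed or Generator; the pipeline derives
  per-stage seeds from the master seed via `SeedSequence(master,
  spawn_key=(stage_index,))`, so stages can be re-run in isolation and full
  runs are byte-reproducible (no timestamps in any output).
* Fisher-z transforms clip correlations at 1 − 1e-15 to keep z finite.
* Modules with (numerically) zero variance are excluded from rate ratios
  with a warning; configurations with zero centroid size, constant size
  vectors, empty groups, singular designs, and non-positive-definite
  correlation or covariance matrices are rejected with explicit messages.
* AICc ties break toward smaller K; remaining exact ties resolve to the
  earlier model in the candidate list (stable ordering).
* Problem sizes in the test suite: calibration checks use 400 replicates
  with 199 null draws each; ensemble analyses use 100 jittered trees;
  transition-count recovery uses 20 replicates of 10 trees at 90 tips.
  These sizes give Monte-Carlo standard errors comfortably inside the
  asserted tolerances.

## Known limitations

* No sliding semilandmarks, no 2D-specific paths, no missing-data handling.
* Mk machinery is strictly binary; multi-state characters are out of scope.
* ML transition-rate estimates on few tips are weakly identified for
  saturated characters; see the saturation caveat above.
* The among-module rate test's null preserves the estimated among-trait
  correlation, which at n ≪ p is itself noisy; its pairwise size is near
  nominal in the tested regimes but has no exactness guarantee.
* `--threads` in the CLI is accepted for interface compatibility only; all
  computation is single-threaded BLAS-level numpy, and results never depend
  on it.
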