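# Methods

This note documents the statistical model behind `connstats`, the choices
made where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## The marginal model

For each edge `e` of the connectome the observed Fisher-Z connectivity
`y_e` (one value per subject) is modelled as

    y_e = X β_e + ε_e,

where `X` is a shared subjects × p design (intercept, predictor of interest,
nuisance covariates) and the errors are dependent within clusters
(acquisition site, family) but independent across clusters. Point estimates
are plain OLS, `β̂_e = (X'X)⁻¹X'y_e`; no random effects are estimated. The
covariance of `β̂_e` is the Huber–White cluster sandwich

    V_e = (X'X)⁻¹ [ Σ_g X_g' e_{g,e} e_{g,e}' X_g ] (X'X)⁻¹,

summed over clusters `g`, and the statistic of interest is the cluster-robust
t-value `t_e = β̂_e / SE_e`. This "marginal model" trades the efficiency of a
mixed-effects fit for a cost that is a few matrix products across all edges
simultaneously — the reason it scales to 77k outcomes.

**Clustering variable.** The analysis that motivated this package corrects
for "site and family" without stating the estimator's exact grouping. We
cluster on **site** by default — the coarsest level of the site ⊃ family
nesting, whose robust covariance absorbs both dependence sources — and
expose `cluster="family_id"` (or any composite column) as configuration
rather than guessing.

**Small-sample factor.** `CR0` (no correction) is the default, matching the
classic sandwich estimator; `CR1` applies `G/(G−1)·(n−1)/(n−p)`. Both are
verified against statsmodels' cluster covariance in the test suite.

## Wild cluster bootstrap

Edgewise inference uses the wild bootstrap **under the null**: the
restricted model (interest column deleted) is fit once; each replicate draws
one Rademacher sign `v_g ∈ {±1}` per cluster and forms
`y* = X_r β̂_r + v ⊙ ê_r`, then the full model is refit on `y*` and the
cluster-robust t of the interest coefficient stored. Two contracts matter:

* **Null-restricted residuals** — "bootstrap under the null" means the
  resampled outcomes satisfy the null exactly, so the null t distribution is
  centered without recentring tricks.
* **Shared signs across edges** — the same `v` applies to every edge within
  a replicate. This preserves the cross-edge dependence of the t-vector,
  which the Westfall–Young correction downstream needs; drawing fresh signs
  per edge would destroy the maxT null.

Implementation: because `X_r β̂_r` lies in the column space of `X`, the
bootstrap residual is `(I − H)(v ⊙ ê_r)`, and both the interest coefficient
and every per-cluster score sum are *linear in the G cluster signs*. The
whole bootstrap therefore reduces to `(B × G)` by `(G × …)` products over
cluster-level precomputations — no per-replicate refit. The literal
refit-loop implementation is kept in the code base and the test suite
asserts exact (1e-14) agreement between the two routes.

p-values use the plug-in count `p = #{|t*| ≥ |t|}/B` (ties count against
rejection; p can be exactly 0 at resolution 1/B), with the positively biased
`(k+1)/(B+1)` estimator available.

## Network Level Analysis

Hypotheses live at the level of canonical resting-state networks, not single
edges. Small interdigitated networks are merged before inference (five
motor-related networks → SM; salience + parietal memory → SAL/PMN; lateral +
medial visual → VIS) so enrichment is not biased toward large networks.

* **Pairs** (including within-network "pairs"): Welch's t of the pair's edge
  t-values against all connectome t-values. Positive = enrichment, negative
  = depletion; inference is two-sided.
* **Whole networks**: Welch's t of |t| over the edges *incident* to the
  network versus |t| over the connectome; one-sided (enrichment), since
  depletion of |t| is not interpreted. Whether "the network's edges" means
  incident or strictly within-network edges is ambiguous; both are
  implemented (`edge_set="incident"` default, `"within"` optional).
* **Reference group**: the connectome-wide comparison *includes* the pair's
  own edges, as the method was described; validity rests on applying the
  identical statistic to every bootstrap replicate, not on two-sample
  independence. A disjoint-complement reference is available.
* **FWER**: Westfall–Young step-down maxT on the bootstrap null Welch
  statistics, pairs and whole networks corrected as separate families (they
  are reported as separate analyses). Hypotheses whose edge set has < 2
  edges are excluded from the family (statistic undefined), and exactly-zero
  mean differences are defined as statistic 0 (degenerate all-equal input).

Welch computations are performed on mean-centered values (shift-invariant,
numerically exact at degenerate inputs) via grouped sum/sum-of-squares
reductions, so the B × (pairs) null matrix costs one pass over the null t
matrix.

## Spin tests

Similarity of two cortical parcel maps is tested against a rotational null:
random Haar rotations of the parcel centroids (QR of a Gaussian matrix, det
forced to +1), the right hemisphere receiving the left's rotation mirrored
through the sagittal plane, and each rotated centroid assigned the value of
the nearest original parcel (which also absorbs data-free regions such as
the medial wall into the nearest parcel; sources may repeat). Comparisons
use cortical parcels only — subcortical parcels carry no surface geometry.

The default mode rotates **both** maps independently per iteration and
correlates the two null maps; the conventional rotate-one variant is
provided since published descriptions are ambiguous about which was used.
The two-tailed p counts strict exceedances, `p = #{|r| < |r_∅|}/N`, with a
`(k+1)/(N+1)` option. Display thresholding (50th–95th percentile) is map
metadata only and never touches statistics. Note that with positional
rotation assignment, swapping the two map arguments in rotate-both mode
gives an equal-in-distribution (not bit-identical) null; the observed r is
exactly symmetric.

Parcel-level spin tests are mildly anti-conservative for very smooth maps:
nearest-parcel resampling attenuates null correlations slightly relative to
the un-resampled observed correlation. Calibration tests at the 333-parcel
scale show ~8% of null comparisons below p = 0.05; maps with very few
effective spatial degrees of freedom would inflate this further.

## Power analysis

The expected within-network Welch statistic for a standardized effect d is

    t_net = (d/σ_stim − t̄) / (σ_t/√n_tot + σ_t/√n_net),

with σ_stim the regression SE of the interest predictor, t̄ and σ_t the mean
and SD of connectome t-values, n_tot the connectome edge count, and n_net
the within-network edge count. The denominator follows the printed additive
form token for token; because the typography of the original expression is
ambiguous, a quadrature (root-sum-of-squares) variant sits behind
`denominator="quadrature"`. `t_net` is ranked against a null family of
Welch statistics with Westfall–Young step-down, and **power = 1 − P** — a
rank-based surrogate for the classical power integral, implemented exactly
as defined and documented as such. The conversion d = t/√n reproduces the
anchor effect size (t = 4.35, n = 24 → d = 0.89).

Since the original bootstrap null came from restricted-access cohort data, a
synthetic null is provided: each replicate draws n_tot independent edge
t-values from N(t̄, σ_t²) and computes the within-network Welch statistics
for disjoint edge blocks. Minimum detectable d is found by bisection
(tolerance 1e-4) on the monotone power-vs-d curve; published
minimum-detectable tables that depend on the real-data null are explicitly
out of scope.

## Synthetic data

The generator produces the structures the analysis assumes and nothing more:

* **Parcellation**: Fibonacci lattices on a unit sphere per hemisphere
  (333 cortical + 61 subcortical by default; the left hemisphere takes the
  extra parcel for odd counts), networks as spherical-cap Voronoi cells of
  quasi-uniform seed directions, mirrored across hemispheres. Contiguous
  caps give parcel maps real spatial autocorrelation, so spin nulls face a
  non-trivial exchangeability problem; independent random labels would make
  them trivially exchangeable.
* **Cohort**: subjects nested in families nested in sites (families are
  runs of `1 + Poisson(mean_family_size − 1)`, so nesting holds by
  construction); day-of-scan stimulant exposure Bernoulli(0.058); ordinal
  sleep 1–5; age, sex, and lognormal mean-FD nuisance covariates.
* **Connectivity**: `z_e = baseline_e + β_stim·stim + β_sleep·sleep +
  β_int·stim·sleep + u_site,e + w_family,e + ε`, with block-constant
  effects over merged-network pairs, independent Gaussian site/family
  intercepts per edge, and i.i.d. edge noise. Defaults: within-network
  baseline 0.30 vs 0.10 between (Fisher-Z); site and family SD 0.03 each and
  noise SD 0.15 — intra-cluster correlation magnitudes are not reported for
  the motivating cohort, so these are plausible free parameters chosen once
  (cluster share ≈ 7% of edge variance). The default planted pattern
  mirrors the reported stimulant signature: −0.030 within SM, +0.030 for
  SM–SAL/PMN, −0.011 per sleep category within SM; when the planted block
  covers ≥ 2% of edges these are the 98th-percentile edgewise magnitudes.
* **Time series**: i.i.d. multivariate-normal frames whose correlation is
  `tanh` of the target Fisher-Z vector (so sample connectivity is unbiased
  for the target, with Fisher variance 1/(n−3)); FD traces have a quiet
  baseline with Bernoulli motion spikes above 0.2 mm. Non-positive-definite
  targets fail with a shrinkage hint. No BOLD spectra, drift, or
  respiration are simulated.
* **Reference maps**: network indicator loadings plus a squared-exponential
  Gaussian random field (length scale 0.5 chord ≈ 29°) evaluated in
  canonical left-hemisphere coordinates, making the smooth component
  bilaterally symmetric — the structure the mirrored-rotation null
  preserves. Fields with only a handful of spatial degrees of freedom (e.g.
  pure dipoles) are *not* a valid stand-in for cortical maps: every map is
  then a rotated copy of one pattern and resampling attenuation dominates
  the null.

What passing tests show — and don't. Calibration and recovery suites run on
this generator: uniform edgewise bootstrap p-values, NLA family-wise error
at nominal level, uniform spin p-values on independent maps, and >80%/>90%
recovery of planted blocks at reported effect magnitudes with n = 2,000
subjects. Real data differ in ways the generator ignores (non-Gaussian edge
noise, heteroskedastic sites, motion-correlated effects, hemispheric
asymmetries), so these results demonstrate the *procedures* are correct and
calibrated under their stated assumptions, not that the assumptions hold in
any particular cohort.

## Numerical and engineering choices

* Canonical edge order: row-major upper triangle, `k = i·n − i(i+1)/2 +
  (j−i−1)`; round-trip identity is property-tested to n = 500.
* FD uses the 50 mm small-angle rotation convention; frames exactly at the
  0.2 mm threshold are retained (exclusion is FD > threshold); censoring
  drops frames (no interpolation); subjects under the frame minimum raise a
  typed exclusion signal rather than being silently truncated.
* Only the interest coefficient's β/SE/t are stored by default
  (`store_full=True` keeps all coefficients) — memory at 77k edges.
* Simulation scales in the test suite (60-parcel connectomes, B = 200–500,
  50–200 simulations) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances in the calibration claims are meaningful.
* Degenerate inputs: constant parcel series, |r| = 1 edges, single-cluster
  designs, rank-deficient (restricted) designs, constant maps, and empty
  null families all raise typed errors naming the offending object.
* Pipeline determinism: every stage's seed is derived from the master seed
  by hashing the stage name; reruns with the same configuration are
  byte-identical, and the provenance record stores the config hash plus
  content hashes of all artifacts.

## Known limitations

* The wild cluster bootstrap is asymptotic in the number of clusters; with
  very few sites (< ~10) its edgewise p-values become granular
  (2^G distinct sign patterns) and NLA conservative.
* `min_detectable_d` inherits the rank resolution of its null (1/B); values
  below the null's resolution are reported at bisection tolerance.
* The spin test's nearest-parcel reassignment is lossy at coarse
  parcellations (see above); vertex-level spins and variogram-matched
  surrogates are out of scope.
* CIFTI adapters (`read_ptseries`/`read_pscalar`) are thin conveniences and
  require nibabel; all first-class I/O is plain text.
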