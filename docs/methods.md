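# Methods

This note records the statistical model, the numerical choices, and
the design decisions behind `ordstar`, in the spirit of the model
documentation shipped by mature statistical packages.  It states no
empirical claim that the test suite or `scripts/acceptance.py` does
not itself compute.

## Model

The outcome is a 3-level ordinal classification of the food
consumption score (FCS): *insecure* (FCS <= 35.5), *vulnerable*
(35.5 < FCS <= 49), *secure* (FCS > 49); band upper bounds are
inclusive.  Internally levels are coded insecurity-ascending
(0 = secure, 1 = vulnerable, 2 = insecure).  Under the cumulative
link `P(Y <= r) = F(theta_r - eta)` this makes positive linear
effects raise the probability of the more insecure levels, which is
the sign convention of the reported coefficient tables.  The coding
direction is recorded in every fitted object and is switchable; note
that the latent-FCS motivation of the threshold model (where the
latent variable is the score itself and the thresholds are the FCS
cuts) implies the opposite category order — the two readings cannot
hold simultaneously, and we follow the sign convention because
reproducing the coefficient table's interpretation is the analysis
goal.

The latent predictor combines:

* **Parametric block.**  Treatment-coded factor dummies and raw
  numeric columns; unpenalized (diffuse prior).  No intercept — the
  two thresholds absorb it, and `theta_2 = theta_1 + exp(delta)` is
  estimated to keep the ordering strict.
* **P-splines.**  Cubic B-splines on *k* = 20 equally spaced knots
  spanning `[min(x), max(x)]` (boundary knots replicated), giving
  `(k - 1) + 3 = 22` basis columns, with a difference penalty
  `D_d' D_d / tau^2` of order *d* = 2 by default (order 1
  selectable).  "20 knots" counts the distinct knots including both
  boundaries; other software may count differently by +-2 columns.
* **MRF zone effect.**  Zone-incidence design with the
  contiguity-graph Laplacian as penalty (degree on the diagonal, -1
  between neighbours): an intrinsic GMRF prior.  Degree-0 zones
  (islands) carry no penalty information; their structured
  coefficient is removed (fixed at zero) and the zone is served by
  the unstructured term only.
* **Tensor-product smooth.**  Row-wise tensor of two marginal cubic
  B-spline bases over zone centroid coordinates standardized to
  [0, 1] per axis (8 knots per margin by default, 20 selectable),
  penalty `K_lon (x) I + I (x) K_lat` with first-order marginals.
  Distances and coordinates are used raw (no projection); over a
  country-scale extent the distortion is modest and the choice is
  recorded in output metadata.
* **I.i.d. zone effect.**  Zone incidence with identity penalty
  (exchangeable Gaussian effects).

**Identifiability.**  Each smooth absorbs one sum-to-zero constraint
by an orthonormal reparameterization: over observed records for
P-splines, over zones for spatial and i.i.d. blocks (for the tensor,
the zone-level fitted surface sums to zero).  A second-order P-spline
keeps its linear nullspace direction inside the block; the fitter's
edf bookkeeping accounts for it.  After constraint absorption the
MRF, i.i.d. and tensor penalties are full rank on the reduced space
(the tensor's constant nullspace is exactly the absorbed direction).

**Penalty scaling.**  Every penalty is scaled to unit spectral norm
before fitting and the factor recorded; reported variances are mapped
back to the original penalty scale so that MRF and i.i.d. variances
are comparable with the generating values, while the reported
smoothing parameter is `1/tau^2` on the scaled penalty.

## Estimation

Empirical Bayes / penalized likelihood:

1. **Inner loop.**  Fisher scoring on `(theta_1, delta, gamma,
   beta_1, ..., beta_J)` maximizing `loglik - 1/2 sum_j beta_j' K_j
   beta_j / tau^2_j` at fixed variances, with step halving so the
   penalized log-likelihood never decreases.  The expected
   information of each record is assembled from the 2x2 information
   in `(theta_1 - eta, theta_2 - eta)`, which keeps the n x P design
   products as single BLAS calls.  Log-probabilities use
   log-CDF differences with complementary-CDF switching, so deep-tail
   records (|theta - eta| > 6) do not lose precision.
2. **Variance updates.**  `tau^2_j <- beta_j'K_j beta_j /
   (edf_j - null_j)` with `edf_j` the block trace of
   `(Fisher + Penalty)^{-1} Fisher`.  The fixed points of this
   ratio are exactly the stationary points of the Laplace-approximate
   restricted likelihood.
3. **Stopping rule.**  A term whose variance reaches 1e-5 (original
   penalty scale) is frozen to its penalty nullspace: an order-2
   P-spline becomes a straight line (df = 1), MRF/tensor/i.i.d.
   terms vanish (df = 0).  Because the ratio update crawls when the
   restricted likelihood is nearly flat toward the boundary (typical
   when two zone-level terms trade off), stalled variances below
   0.05 are additionally subjected to a *boundary test*: the Laplace
   restricted likelihood is compared between the current value and
   the stopping boundary, jointly over all stalled terms (subset
   enumeration, since coordinate-wise decisions are order-dependent
   on a ridge), and the boundary is preferred unless the interior
   wins the one-sided variance test at the 5% level — the critical
   value 1.353 on the log-restricted-likelihood scale is half the
   95% point of the `1/2 chi2_0 + 1/2 chi2_1` boundary mixture that
   the LR statistic follows when a variance sits on the edge of its
   parameter space.  This makes the stop rule an explicit hypothesis
   test rather than an artifact of update dynamics.
4. **Convergence.**  Relative change of the penalized deviance below
   1e-7 *and* relative change of every active variance below 1e-4;
   at most 200 outer iterations, then the best iterate is returned
   flagged non-converged.  Fitting is deterministic; only the
   generator and permutation tests consume seeds.

**Inference.**  The coefficient covariance is the Bayesian posterior
covariance `(Fisher + Penalty)^{-1}`.  Parametric rows report
estimate, SE, `z = est/SE` and a two-sided normal p-value; threshold
SEs use the delta method through the `(theta_1, delta)`
parameterization.  Smooth curves are centered (by the constraint)
with pointwise `+-1.96 SE` bands from the block covariance;
extrapolation beyond the observed covariate range is refused.  Zone
tables report structured, unstructured and total effects with bands
from the joint covariance (including the cross-term), and classify a
zone hot/cold/neutral by whether the total-effect band clears zero.

**Model comparison.**  `GCV = n * deviance / (n - edf_total)^2` with
`deviance = -2 loglik` (saturated constant omitted) and `edf_total =
2 + #parametric + sum_j edf_j`.  GCV values are comparable only
across models fitted to the same data and coding; ties within 1e-8
are broken toward fewer edf.  The functional form is a deviance-based
convention of this package, so its absolute values are not comparable
with other software's GCV.

**Moran's I.**  Binary contiguity weights by default (matching the
adjacency-as-precision convention of the MRF; row-standardized
available), analytic inference by the normal approximation under
randomization, permutation inference two-sided with
`p = (1 + #{|I_perm| >= |I_obs|}) / (M + 1)`, M = 9999 by default.
Zones without data are dropped and the weights re-subset.  Both the
aggregate variable (insecure proportion, mean FCS, modal level) and
the weight mode are user choices, since neither is canonical.

## Synthetic generator

`default_truth()` / `gen_panel()` emulate a three-wave national
household panel: an 8x8 rook-contiguity zone lattice (64 zones,
unit-spaced centroids), 3,835 households allocated to zones by a
Dirichlet(5)-multinomial (unequal allocation, as in multi-stage
surveys), 3 waves (11,505 records).  The generating values are the
published point estimates of the study this package re-implements:
thresholds (-0.3789, 0.4742); factor effects urban -0.3883, literacy
-0.2378, shock 0.0683, fertilizer -0.1324, employment -0.2054, small
land 0.1566; structured variance 0.6104 and unstructured variance
0.0675 (structured share 90.04%).  The structured field is drawn from
the intrinsic GMRF (eigen-sampling on the sum-to-zero subspace); the
unstructured field is centered i.i.d. normal.  Factor prevalences
(urban 13% per the 43/333 urban enumeration areas; literacy 45%,
shock 50%, fertilizer 35%, employment 20%, small land 55%) and the
continuous-covariate laws (dependency ratio ~ Gamma(2, 0.6) capped at
8; head age ~ N(45, 15) clipped to [18, 90] and aging 2 years per
wave) are the package's choices of survey-realistic values.  The
true smooths are a saturating dependency-ratio effect
`0.25 tanh(1.5(d - 1))` and an early-marriage age hump
`0.35 exp(-((a - 30)/15)^2)`; a linear wave trend of -0.07 per wave
encodes declining insecurity.  FCS values are drawn uniformly within
the band implied by the sampled level — sufficient to exercise the
categorization round trip, *not* a model of real scores.  Optional
MCAR missingness exercises the longitudinal-mean imputation.

**Calibration.**  A single latent offset is found by 1-D search so
the implied marginal level proportions (computed by a deterministic
Monte Carlo with the uniform zone allocation, the expectation of the
Dirichlet) match the published margins (25 / 27.1 / 47.9%) in least
squares.  A known limitation: with the published thresholds (gap
0.853) and the realized iGMRF field variance (latent s.d. ~0.85),
the maximum attainable vulnerable share is about 24.5%, so the
calibrated generator runs ~3 points low on *vulnerable* (and
correspondingly ~1-2 points high on the neighbours); the insecure
and secure shares land within ~2-3 points.  No single offset can
remove this compression, and the generating variances are fixed
study conditions, so the tests assert the attainable behaviour.

**What passing tests show.**  The generator matches the study's
design dimensions, effect sizes and spatial structure, but not the
survey's sampling weights, within-household longitudinal correlation
(not modeled, as in the original analysis), item-level FCS
construction, or real-map contiguity (a lattice stands in for the
zone map).  Recovery results on synthetic data therefore validate
the estimation machinery, not the substantive findings on the real
survey.

## Problem sizes used in checks

The recovery study runs 10 replicates at the full design size
(11,505 records); model-selection and stop-rule studies run 20
replicates at 3,000 records (1,000 households), sizes at which the
relevant effects are comfortably detectable while the whole suite
stays fast.  At the full size a single geo-additive fit
(7 parametric columns, two 21-column smooths, 63 + 63 zone
coefficients) takes a few seconds.

## Known limitations

* The share of spatial variance attributed to the structured term is
  estimated with a downward tilt of roughly 5-10 points at 64 zones:
  the rough (high-frequency) component of an iGMRF field is nearly
  indistinguishable from exchangeable noise at the zone resolution,
  and the restricted likelihood is correspondingly flat (verified by
  profiling in development).  The acceptance suite's +-10-point check
  passes, but with little margin.
* A frozen second-order P-spline represents lines in the coefficient
  index, which differ from exactly-x-linear functions by a small
  boundary (Greville) effect; the discrepancy is far inside the
  reported bands.
* GCV values are package-specific (deviance-based); only
  within-package comparisons are meaningful.
* The cumulative model assumes proportional (parallel) effects across
  the two thresholds; no partial proportional-odds relaxation is
  provided.
* No MCMC / full-Bayes path and no household-level random effects.
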