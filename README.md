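# ordstar

Ordinal geo-additive regression for areal panel data: cumulative-probit
(or logit) structured additive models with Markov-random-field and
tensor-product spatial smooths, P-splines, empirical-Bayes smoothing,
GCV model comparison, Moran's I, and hot/cold-spot zone classification.

## The problem

Household food insecurity is commonly measured by the food consumption
score (FCS), a weighted weekly food-group frequency, and classified
into three ordered levels — *insecure*, *vulnerable*, *secure* — by
score cut points (here the locally adjusted cuts 35.5 and 49).
Surveys of this kind are panels: thousands of households observed over
several waves, nested in administrative zones.  Two questions drive
the analysis: which household characteristics shift the probability of
being at a higher insecurity level (often non-linearly), and where the
insecure zones cluster geographically, so that interventions can be
targeted at hot spots.

## The model

The observed level of household *i* is a categorized latent variable
`D_i = eta_i + eps_i` with ordered thresholds `theta_1 < theta_2`:

    P(Y_i <= r) = F(theta_r - eta_i),          r = 0, 1

with `F` the standard normal CDF (probit; `eps ~ N(0, 1)`) or the
logistic CDF.  The latent predictor is structured additive:

    eta_i = x_i' gamma + sum_j f_j(z_ij) + f_str(s_i) + f_unstr(s_i)

* `gamma` — linear effects of categorical factors (diffuse prior);
* `f_j` — P-splines: cubic B-splines on 20 equally spaced knots with a
  second-order random-walk penalty `beta' D2'D2 beta / tau^2_j`;
* `f_str` — structured zone effect: intrinsic Gaussian Markov random
  field whose precision is the zone contiguity-graph Laplacian
  (neighbours share a boundary), or alternatively a two-dimensional
  first-order random-walk tensor-product P-spline of zone centroids;
* `f_unstr` — exchangeable (i.i.d.) Gaussian zone effects.

Estimation is empirical Bayes: penalized Fisher scoring for all
coefficients at fixed variances, REML-type updates
`tau^2_j <- beta_j'K_j beta_j / (edf_j - null_j)` for the smoothing
variances, and a restricted-likelihood boundary test that freezes a
term to its penalty nullspace when its variance falls to the stopping
threshold (1e-5) — a second-order P-spline degrades to a straight
line, spatial terms to zero.  Models are compared by
`GCV = n * deviance / (n - edf_total)^2`; zone clustering is tested
with global Moran's I; a zone is a *hot spot* when the 95% band of its
total spatial effect lies above zero on the insecurity-ascending
scale (and a *cold spot* below).

Because the real survey microdata require registered access, the
package ships a synthetic generator that emulates the study design
(64 zones, 3,835 households x 3 waves = 11,505 records, published
effect sizes and spatial variances) with the full generating truth
kept alongside, so every stage is testable end to end.

## Worked example

```python
import ordstar as o
from ordstar.model import ModelSpec, Parametric, PSpline, MRF, IID, fit
from ordstar.moran import SpatialWeights, morans_i
from ordstar.prep import zone_aggregate

truth = o.default_truth(seed=0)                    # 8x8 zone lattice, known fields
data, _ = o.gen_panel(truth, n_households=1000, seed=42)

m = morans_i(zone_aggregate(data, "insecure-proportion"),
             SpatialWeights.from_graph(truth.graph), permutations=999, seed=1)
print(f"Moran's I = {m.I:.4f} (permutation p = {m.p_permutation:.4g})")

spec = ModelSpec(terms=[
    Parametric(["urban", "read_write", "shock", "employed", "small_land", "wave"]),
    PSpline("dependency_ratio"), MRF(), IID()])
fm = fit(data, spec, truth.graph)
print(f"GCV = {fm.gcv:.4f}  edf = {fm.total_edf:.2f}")
print(fm.coef_table().round(4))
print(f"structured share = {fm.variance_partition():.2f}%")
```

prints

```
Moran's I = 0.5075 (permutation p = 0.001)
GCV = 1.7564  edf = 63.18
                 estimate      se       z       p signif
theta_1           -0.3302  0.0760 -4.3467  0.0000    ***
theta_2            0.5500  0.0762  7.2144  0.0000    ***
urban[yes]        -0.2882  0.0695 -4.1434  0.0000    ***
read_write[yes]   -0.2729  0.0466 -5.8497  0.0000    ***
shock[yes]         0.0969  0.0465  2.0841  0.0371      *
employed[yes]     -0.1327  0.0597 -2.2235  0.0262      *
small_land[yes]    0.1250  0.0468  2.6700  0.0076     **
wave              -0.1132  0.0276 -4.1025  0.0000    ***
structured share = 81.76%
```

The strongly positive Moran's I says neighbouring zones have similar
insecurity rates.  Negative coefficients (urban residence, literacy,
employment) reduce the probability of the higher insecurity levels;
shocks and small land ownership increase it; the negative wave effect
is the decline of insecurity over survey years.  The structured share
is the fraction of the zone-level variance carried by the spatially
smooth field rather than zone-idiosyncratic noise — the figure that
tells policy to target *regions*, not isolated zones.  `zone_effects()`
returns the per-zone effects, bands and hot/cold classification;
`smooth_curve()` exports each non-linear effect with its 95% band.

A command-line interface wraps the same operations
(`ordstar simulate | describe | moran | fit | run`); `ordstar run
--config cfg.yaml` executes the whole workflow (prepare, describe,
Moran's I, all model variants, GCV comparison) and writes every table
as CSV plus a plain-text summary.

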