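# Methods

## The model

`sekrige` analyses point-referenced micronutrient survey data with a
three-level linear mixed model on the natural-log scale. For individual
*k* in household *j* of cluster *i* at location *x_i*:

    log z_ijk = mu + S(x_i) + H_ij + E_ijk

* `mu` — the only fixed effect, a constant mean (log ng/mL). The model
  assumes stationary variation about this mean with no trend, which should
  be checked on cluster means before fitting.
* `S` — a zero-mean stationary, isotropic Gaussian random field over
  cluster locations with variance `sigma2_c` and Matérn correlation.
  Isotropy means dependence through distance only; anisotropic or
  non-stationary covariances are out of scope.
* `H_ij` — iid between-household (within-cluster) effects, variance
  `sigma2_h`.
* `E_ijk` — iid between-individual (within-household) residuals, variance
  `sigma2_e`; this component absorbs analytical measurement error.

The Matérn correlation is parameterised in the geoR convention,

    rho(h) = [1 / (2^(nu-1) Gamma(nu))] (h/phi)^nu K_nu(h/phi),

chosen because `nu = 0.5` then reduces exactly to the exponential model
`exp(-h/phi)` and the effective range (correlation 0.05) is about `3 phi`.
The alternative sqrt(2 nu)-scaled convention is deliberately not used: with
the reference fit (`nu = 0.5`, `phi = 39.4 km`) only the geoR convention
reproduces the ~120 km limit of spatial dependence between cluster means.
Evaluation goes through the exponentially scaled Bessel function in log
space so large `nu` does not overflow.

## Parameters and defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| `mu` | mean log concentration | log ng/mL | log(78.4) |
| `sigma2_c` | between-cluster variance | log scale | 0.15 |
| `sigma2_h` | between-household variance | log scale | 0.018 |
| `sigma2_e` | between-individual variance | log scale | 0.028 |
| `nu` | Matérn smoothness | — | 0.5 |
| `phi` | Matérn distance parameter | km | 39.4 |
| thresholds | GPx3 / IDI / KD deficiency cut-offs | ng/mL | 84.9 / 64.8 / 30 |
| grid resolution | kriging lattice spacing | km | 5 |

The generative defaults are the published national-survey fit for plasma Se
among Malawian women of reproductive age; `mu` makes the marginal lognormal
median 78.4 ng/mL. The GPx3 threshold is 84.9 ng/mL (some summaries of the
same thresholds circulate as 86.9; we use 84.9 consistently, and the value
is configurable). The default kriging resolution is 5 km — a desk-scale
choice; the production-scale 0.5 km grid is supported by setting
`grid_resolution_km: 0.5`.

## Estimation

Variance components and `phi` are estimated by REML: the likelihood of the
n−1 error contrasts, removing the bias of estimating `mu`. The objective is

    l_R = -1/2 [ (n-1) log 2pi + log|V| + log(1'V^-1 1) + y'Py ].

Evaluation exploits the nesting: with A the household+individual part
(block diagonal, closed-form eigenvalues `sigma2_e` and
`sigma2_e + m sigma2_h` per household of size m) and the cluster field
entering through a k×k Woodbury correction, one evaluation costs O(n + k³)
for k clusters. This is algebraically identical to the dense-matrix form,
which the test suite verifies to 1e−8 on small instances.

Numerical choices:

* Optimisation on log-transformed parameters (log variances, log phi) with
  L-BFGS-B; three starting points (a method-of-moments ANOVA start plus an
  equal-split and a cluster-heavy start at different `phi` scales) because
  REML surfaces of Matérn models can be multimodal.
* Convergence tolerance 1e−6 on the log-likelihood; variances floored at
  1e−10 so V stays positive definite; `phi` bounded by [1e−3, 2]× the
  maximum inter-cluster distance.
* A spatial variance estimated at the floor is reported as 0 with
  `phi_identifiable = False` — `phi` means nothing when `sigma2_c = 0`.
* Smoothness by profile likelihood over a grid (default
  {0.1, 0.25, 0.5, 1.0, 1.5, 2.0}); ties break toward smaller `nu`
  (parsimony). Standard errors of variance components are not computed.
* With one individual per household, `sigma2_h` and `sigma2_e` are not
  separately identifiable; the generator therefore defaults to two
  individuals per household.

## Prediction

Ordinary kriging with the plug-in REML parameters, global neighbourhood
(every observation in every solve; one factorisation of the augmented
system is reused for all grid nodes). The prediction target is an
*unobserved individual's* value: the target variance is the full
`sigma2_c + sigma2_h + sigma2_e`, while target–support covariances carry
only the spatial component. This matches the use of the maps — the
probability that an individual woman's plasma Se falls below a threshold —
rather than predicting a cluster or household mean. The OK prediction m and
variance s² define the Gaussian conditional distribution of the log value;
`exp(m)` is reported as the median-unbiased central value (the lognormal
median, not the mean `exp(m + s²/2)`).

Exceedance probabilities are `Phi((log T - m)/s)` per threshold; with
`s² = 0` the distribution is a point mass and the strict-inequality
convention `1[exp(m) < T]` applies. Probabilities are classified on a
five-phrase calibrated verbal scale with default interior edges
{0.10, 0.33, 0.66, 0.90}; the edges are configurable and always written
into the legend JSON, since the verbal scale is a communication device,
not a statistical one.

## Validation

Leave-one-out cross-validation with plug-in parameters (no per-fold refit —
standard practice and a known source of mild optimism). All folds come from
the bordered precision matrix of the global OK system: with B the leading
n×n block of the inverse augmented matrix, `zhat_i = z_i − (Bz)_i / B_ii`
and `s²_i = 1/B_ii`, identical to explicit per-fold solves (verified in
tests). The diagnostic is the standardized squared prediction error
`theta_i = (z_i − zhat_i)²/s²_i`: approximately chi-square(1) under a valid
model, so mean ≈ 1 and median ≈ 0.455. Because kriging errors are
correlated, the 95% reference interval for the *median* theta is computed by
Monte-Carlo simulation from the fitted model on the observed design rather
than from independent-chi-square theory. Folds with singular systems are
flagged and excluded; more than 1% flagged aborts the summary. Normality of
standardized errors is reported descriptively (skewness, excess kurtosis,
QQ data) with no hypothesis-test verdict.

## Synthetic surveys

The generator draws cluster locations uniformly in the region (default: a
160 km × 850 km rectangle, a Malawi-like aspect ratio, in arbitrary planar
km), flags a configurable fraction urban, nests a balanced number of
households and individuals, and simulates the outcome by inverting the
model above. Wealth quintiles are independent uniform 1–5 unless a
monotone `wealth_gradient` on `mu` is requested. Exact duplicate cluster
coordinates are resampled rather than jittered, so spatial covariance
matrices are positive definite by construction. Random draws occur in a
fixed order (design, then S, then H, then E) to keep seeds portable.

What the generator does *not* emulate: probability-proportional-to-size
selection weights, household replacement rules, enumeration-area coordinate
displacement, non-response, demographic age structure, and any
outcome–covariate relationship beyond the optional wealth gradient and the
spatial field itself. Passing tests therefore demonstrate that the
machinery is correct *under the model's own assumptions*; they cannot show
that the model is adequate for a particular real survey — that is what the
cross-validation diagnostics are for.

## Problem sizes

The recovery experiment in `scripts/acceptance.py` uses 20 replicates of a
102-cluster × 9-household × 2-individual design (1,836 observations), with
the smoothness profile over {0.25, 0.5, 1.0, 2.0}; this matches the scale
of the reference survey among women of reproductive age. The calibration
checks use ~600 observations; the default pipeline grid is 5 km. These
sizes were chosen so a full run completes in minutes on a single CPU while
keeping the designs at the reference scale where it matters.

## Known limitations

* Smoothness selection by profile likelihood is noisy at ~100 clusters: in
  simulation from the `nu = 0.5` model the true value wins the profile in
  roughly half to two-thirds of replicates, with most misses going to the
  neighbouring grid values. The *modal* selection across replicates is
  stable at 0.5. This is a property of the information content of the
  design, not of the optimizer (checked against exhaustive restarts).
* `phi` estimates are right-skewed at this design scale; means over
  replicates sit within a few percent of the generative value, single fits
  can be off by ±50%.
* Global kriging is O(n³) once per dataset and fine to ~3,000 observations;
  larger supports would need a moving neighbourhood, which is not
  implemented.
* No survey-weight adjustment is applied to prevalence estimates by
  default (a `survey_weight` column, if present, produces weighted
  percentages alongside).
* GeoJSON is the only supported geometry format and CSV the only raster
  output; coordinates must already be projected to planar km.
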