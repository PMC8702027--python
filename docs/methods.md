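# Methods

`sedscreen` implements an integrated screening analysis for contaminated
sediments: in vitro concentration–response data from sediment extracts
are reduced to points of departure (PODs), integrated into ToxPi hazard
scores, tested for spatial association, cross-predicted against PAH
chemistry, and compared against traditional risk-based remediation
goals.  This note documents the models, the defaults and why they were
chosen, and what the synthetic study does and does not emulate.

## Concentration–response model and PODs

Responses are scaled by the pooled vehicle-control mean per endpoint, so
the vehicle band becomes 1 ± sd/mean.  Each sample × endpoint series is
fit with a four-parameter Hill/logistic curve in log10 dilution,

    f(x) = bottom + (top − bottom) / (1 + 10^(h (m − log10 x))),

by bounded least squares with an analytic Jacobian and five EC50
multi-starts spread over the tested range (ties broken by lowest RSS,
then smallest |h|).  The reported `hill` is signed: positive when the
response rises with extract concentration.  The POD is the smallest
dilution in the tested range at which |f − 1| exceeds one vehicle SD,
solved from the logistic inverse (bracketed root finding as fallback).
Conventions for the edge cases:

* curve already outside the band at the lowest tested dilution → POD
  clamped there, flagged `extrapolated-low` (no unbounded extrapolation);
* no crossing in range, or non-converged fit → censored at the maximum
  tested dilution;
* a zero-width band (vehicle SD = 0) is exited everywhere by any
  non-flat curve, which lands in the extrapolated-low clamp.

The continuous fitted curve is searched, not only the tested dilutions,
and "one SD" means the SD of the pooled vehicle wells (not the SEM).

## ToxPi integration

Within each endpoint, active log10 PODs are inversely rescaled so the
highest POD in the dataset scores 0 and the lowest scores 1; censored
PODs score 0, as do endpoints whose active PODs span zero range.
Per-endpoint/log scaling is the package default (matching common ToxPi
practice); pooled and linear-scale alternatives are available through
`scale_pods(per_endpoint=..., log_scale=...)`.  Slice weights default to
equal; the overall score is the weighted mean, cell-type scores are
unweighted means of member slices, and rank 1 is the highest overall
score with ties broken by input order.  Heatmap ordering uses
average-linkage hierarchical clustering on Euclidean distance.

## Spatial statistics

Geographic distance is haversine (km) on WGS84 lon/lat.  The Mantel
statistic is the Pearson correlation of upper-triangle entries of the
geographic distance matrix against a feature dissimilarity matrix —
squared differences for one feature, 1 − Spearman correlation of sample
feature vectors for the global test.  The null distribution permutes
rows/columns of the feature matrix; the test is one-sided (greater),
since the alternative of interest is positive association of distances,
with p = (1 + #{perm ≥ obs}) / (B + 1) and B = 10,000 by default.  An
exhaustive mode enumerates all n! relabelings for small n.
Benjamini–Hochberg adjustment is applied across features.

Ordinary kriging uses a spherical semivariogram fit by weighted least
squares (weights = pair counts) to the method-of-moments empirical
semivariogram; the lag size is accepted in km (2 km default at this
site spacing; tools that work in geographic degrees near 29–30° N use
≈ 0.003°, which is the same order once converted at ≈ 111 km/degree).
Values are log10-transformed before kriging by default (scores bounded
at 0 receive a 1e-6 offset).  The kriging system is solved in
covariance form with a Lagrange multiplier, so weights sum to 1 by
construction and prediction at a data site is exact when the nugget is
zero.  Duplicate coordinates are averaged with a warning.  The default
map grid is 100 × 100 over the bounding box plus a 5% margin.

## Cross-prediction

Bioactivity (log10 POD, censored entries at the maximum tested
dilution) and chemistry (log10 of concentration plus half the minimum
positive value per column) matrices are cross-predicted by multivariate
ridge regression with a single shared penalty, evaluated by
leave-one-out cross-validation.  The held-out row is removed before any
standardization (the stricter, leakage-free reading); columns are
standardized on each training fold; predictions are returned to the
original scale with the training fold's mean and SD.  The penalty grid
is 30 log-spaced points over [1e-3, 1e3] × n_predictors, chosen to
minimize fold-standardized mean-squared prediction error.

Per-feature significance is the Pearson correlation between the
cross-validated predictions and observations with a **one-sided
(greater)** p-value, BH-adjusted within each prediction direction.  The
one-sided choice is deliberate: with a shared penalty, LOOCV
predictions of signal-free features are systematically anti-correlated
with the held-out values (shrinkage toward the training mean, whose
leave-one-out form anti-correlates with the held-out observation), and
a two-sided test reports that artifact as "significant prediction".
Positive correlation is what prediction skill means here.

## Risk screening and remediation goals

Alkylated homolog concentrations are added to their parents
(conservative), totals excluded.  HI and CR are sums of concentration /
screening-level ratios; screening levels are defined at HQ = 1 and
1e-6 risk respectively, so CR is reported directly in cases per
million.  Two scenarios are carried: recreational sediment contact and
residential soil (deposited sediment), with residential levels the more
stringent.  **The packaged screening-level table is illustrative**
(realistic orders of magnitude for the 16 priority PAHs; residential
cancer SL for benzo[a]pyrene 110 ng/g, recreational 50× higher, and so
on); real assessments must load authoritative values via
`load_tox_params`.

Remediation is expressed as a dilution (fold-reduction) factor, valid
because HI, CR and endpoint activity are all monotone in concentration.
The traditional factor is max(HI, CR, 1); equality with the goal counts
as compliant.  The bioactivity goal is the dilution at which at most
10% of endpoints remain active ("active" means dilution ≥ POD; censored
endpoints count in the denominator and enter the percentile pool at
+∞).  The goal starts from the interpolated (type-7) 10th percentile of
the POD pool; because that interpolated value can sit above the
(⌊0.1 m⌋+1)-th order statistic (e.g. m = 34 endpoints: 10th percentile
between the 4th and 5th smallest PODs, leaving 4/34 ≈ 11.8% active),
the goal is capped at the largest POD value whose active fraction is
compliant.  This keeps the protectiveness guarantee exact —
fraction-active ≤ 10% at the goal for every sample — which we treat as
the binding requirement.  Baseline exposure is the undiluted extract
(dilution 1.0), so the factor is 1/goal, floored at 1.

## Synthetic study design

The generator emulates a 46-sample, three-region coastal survey
(Houston Ship Channel, Mud & Clear Lakes, Galveston Bay at 16/12/18
samples), 34 endpoints in 5 cell types, and 40 analytes (16 priority
parents, 21 alkylated homologs, 3 exact totals).  Structure:

* **Latent contamination field** — Gaussian with exponential covariance
  (range 15 km, marginal SD 1) plus region offsets (+0.8 ship channel,
  +0.4 lakes, 0 bay), sampled exactly via Cholesky.
* **Chemistry** — parent log10 concentrations are affine in the latent
  field with deliberately weak loadings (U(0.12, 0.28)) and large
  idiosyncratic noise (SD 0.8 log10): individual analytes are mostly
  sample-specific and the shared spatial structure is carried by the
  latent field (and, relatively, by class totals which average out the
  noise).  Homologs are fixed fractions of their parents with lognormal
  jitter; totals are exact sums.  A consequence worth knowing: at 46
  samples the per-analyte Mantel screen typically detects *no*
  individual analyte after FDR adjustment — loadings strong enough for
  per-analyte spatial detection would also make every analyte
  significantly predictable from bioactivity, erasing the planted
  prediction asymmetry.  The planted spatial covariance is instead
  verified directly against the analytic model in the test suite.
* **Bioactivity** — each endpoint's log10 EC50 decreases with a
  weighted chemical burden (six analytes, Dirichlet weights) and with a
  non-PAH driver: a per-sample latent correlated 0.8 with the
  contamination field but independent of the measured analytes,
  representing unmeasured co-located contaminants.  Eleven endpoints are
  chemistry-dominated, nineteen non-PAH-dominated, four are flat nulls.
  Endpoint × sample potency jitter is 0.25 log10.  Baseline potencies
  (log10 EC50 ∈ U(−0.9, 0.1) before burden shifts) give realistic POD
  sparsity: roughly a third of sample × endpoint pairs are inactive.
* **Plates** — 8-point 3-fold dilution ladder from undiluted extract,
  3 replicates, 12 vehicle wells per endpoint, Gaussian response noise
  SD 0.05 on the vehicle-relative scale (vehicle mean 1.0, since the
  analysis consumes vehicle-scaled data anyway).  The recorded true POD
  is the analytic band crossing of the noiseless curve.

This construction reproduces, as emergent behavior rather than
hard-coded numbers, the study-level patterns the analysis is meant to
expose: overall bioactivity ranks samples by latent contamination;
chemistry predicts bioactivity far better than bioactivity predicts
individual analytes; every sample is bioactive at baseline while only a
minority exceeds 1-per-million cancer risk; and chemistry-based cleanup
leaves most samples bioactive while bioactivity-based cleanup drives
residual cancer risk well below 1 per million.

What the generator does **not** emulate: measurement error structure of
analytical chemistry beyond lognormal jitter, plate/batch effects,
non-monotone concentration–response shapes, correlated replicate noise,
censored chemistry (non-detects), or sediment transport.  Passing tests
therefore demonstrate the statistical machinery under the planted
model, not performance on any real survey.

## Problem sizes and numerical choices

Simulation-based checks use the analytic ground-truth PODs (100
simulations for the recovery, asymmetry and region-effect properties;
400 for the cross-prediction power/type-I rates), while curve fitting
is exercised once on the full 46 × 34 plate table; this keeps each
property focused on one stage of the pipeline.  Logistic fits use
tolerances of 1e-10 with at most 200 function evaluations per start;
POD crossings are solved analytically with Brent bisection at 1e-12 as
fallback; the kriging system is solved by a single dense factorization
(n ≤ a few hundred sites).  Quantiles are type-7 (linear
interpolation).  Ties in ranking and clustering are broken by input
order so all outputs are deterministic given seed and configuration.

## Known limitations

* The POD search assumes a monotone fitted curve (true for the 4PL);
  biphasic responses are out of scope.
* Vehicle statistics are pooled per endpoint; per-plate vehicle
  normalization is not modeled.
* The ridge cross-prediction selects a single penalty for all response
  columns, as specified; per-column penalties would likely predict
  better but answer a different question.
* The illustrative screening-level table must not be used for real
  risk decisions.
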