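# Methods

`lakethermal` implements a statistical pipeline for discovering and applying
*lake thermal regions*: groups of lakes that share a seasonal pattern of
lake surface water temperature (LSWT). The pipeline has five stages —
synthetic data generation, ice-aware spline smoothing, cluster discovery,
a portable classification rule, and region-level accounting — each usable
on its own from Python.

## Seasonal archetypes and the synthetic population

Real global LSWT archives (twice-monthly satellite retrievals over many
years) are not bundled with the package. Instead, `lakethermal.synthetic`
generates populations with the statistical structure the analysis assumes.
Each of the nine thermal regions — Northern Frigid (NF), Northern Cool
(NC), Northern Temperate (NT), Northern Warm (NW), Northern Hot (NH),
Tropical Hot (TH), Southern Hot (SH), Southern Warm (SW), Southern
Temperate (ST) — is represented by a latent single-harmonic sinusoid

    f(t) = m + A·cos(2π(t − p)),     g(t) = max(f(t), 0),

with `t` in decimal years and `p` the peak day-of-year (205 for
northern-phase regions, 25 for southern). The realized curve `g` is the
latent curve clamped at 0 °C: wherever `f < 0` the lake is ice-covered and
its surface sits at the freezing point. A two-parameter sinusoid is the
minimal shape that reproduces the four region statistics we calibrate to:
annual mean, annual range, peak phase, and ice fraction.

**Calibration.** For regions whose latent minimum is positive the latent
parameters are simply the target mean and half-range. For freezing regions
the clamp inflates the mean and the range is `m + A` (maximum minus the
0 °C floor), so the parameters are solved from the closed forms

    mean(g) = (m·β + A·sin β)/π,  β = arccos(−m/A),   range(g) = m + A,

by a bracketed 1-D root solve (tolerance 1e-6 °C). The resulting ice
fractions (`arccos(m/A)/π`) land within 0.05 of the reference values
(NF 0.65 vs 0.61, NC 0.54 vs 0.50, NT 0.31 vs 0.29). Two regions with
small reported ice time (NW 1%, ST 5%) cannot freeze under a single
harmonic that also matches their mean and range — the implied latent
minimum is positive — so their archetypes are ice-free; the discrepancy
(≤ 0.05) is within the same tolerance. Tests verify all calibrations
against direct quadrature of the clamped curve rather than the closed
forms used in the solver.

**Population structure.** The default population has 732 lakes apportioned
to regions by the reference percentages (largest-remainder rounding with a
floor of 20 lakes per region so that even the rarest regions support
class-conditional model fits). Each lake draws a Gaussian offset on its
latent mean (sd 0.8 °C) and latent range (sd 1.5 °C), plus iid observation
noise (sd 0.5 °C) on non-ice samples; sub-zero samples are clamped to 0 °C
with the ice flag set. The within-region spreads are package choices: they
make neighbouring regions overlap mildly in curve space while keeping the
generating memberships recoverable, which is the regime the classification
rule is meant for. Sampling is 24 observations per year at mid-fortnight
times `(i + 0.5)/24`, for 16 years by default. All draws come from one
seeded generator in lake order, so populations are bit-reproducible.

What the generator does *not* emulate: retrieval gaps and seasonal biases
of satellite data, multi-year trends, interannual variability in ice
phenology, and non-sinusoidal seasonal shapes (e.g. monsoon-driven double
peaks). Passing tests therefore demonstrate the statistical machinery on
idealized seasonal structure, not robustness to real-data artefacts.

**Relaxation emulator.** `simulate_lswt` maps location and depth to an
LSWT cycle via daily relaxation toward an equilibrium curve,

    T_{i+1} = T_i + (E_i − T_i)·Δt/τ,   τ = τ₀·(1 + depth/depth_scale),

with `E(t)` a sinusoid whose mean is `27 − 0.55·|lat| − 6.5·(elev/1000)` °C
and whose amplitude is `0.03·lat²` capped at 20 °C, peaking in the local
summer. Defaults are τ₀ = 5 days and depth_scale = 10 m, giving shallow
lakes a near-equilibrium response and deep lakes a damped, lagged one. This
is a documented heuristic — a closed-form stand-in capturing the
first-order controls (latitude, elevation, depth) on seasonal LSWT — not a
physical lake model: there is no stratification, ice thermodynamics, wind
or radiation physics. A `mean_warming` offset on `E` supports simple
climate-scenario experiments. The latent state is left unclamped while the
output is clamped at 0 °C with ice flags; tests check the unclamped
dynamics against the exact geometric-convolution solution of the linear
filter and the monotone damping of seasonal range with depth.

## Ice-aware saturated B-spline smoothing

Each series is smoothed with a cubic B-spline basis that places an interior
knot at every observation time. For `N` observations this gives `N + 2`
basis functions — deliberately saturated, so the fit can track any pattern
the sampling can resolve and the coefficient vector is a near-lossless
encoding of the curve.

The ice rule comes first: flagged observations are set to 0 °C, and
sub-freezing unflagged observations are treated as ice detections. Then
every basis function *centred* on an ice-flagged time — centre defined as
the observation time nearest the function's Greville abscissa, with the
boundary functions collapsing onto the first/last observation — has its
coefficient fixed to exactly zero. This removes those basis functions from
the fit while keeping the basis (and hence the coefficient indexing)
identical for every lake on the same grid, which the clustering stage
requires.

The remaining free coefficients solve penalized least squares with a small
second-difference penalty (λ = 1e-4, configurable). The penalty's only job
is to pin down the two extra degrees of freedom of the saturated basis and
tame the boundary; at λ = 1e-4 a noiseless sinusoid is reproduced to
better than 2e-4 °C at the observation times and a constant to 1e-6 °C.
Fits are linear in the data, so scaling/offsetting a series scales/offsets
its coefficients. Because the fitted spline can dip slightly below zero
next to ice intervals, evaluation of an ice-containing fit is clamped at
0 °C.

**Seasonal profiles.** The fitted curve is evaluated on a within-year grid
(default 96 points/year at `(g + 0.5)/96`, on a 365-day leap-free
calendar) for each observed year and averaged pointwise. Evaluation is
clamped to the observation span, so the first/last grid points of the
first/last year reuse the boundary value; with ≥ 4 years the effect on the
average is negligible away from the two outermost grid points.

## Cluster discovery

K-means (Euclidean, k-means++ seeding, best of 50 restarts, empty clusters
re-seeded from the farthest points) runs on the lakes × coefficients
matrix. The number of clusters is selected with the gap statistic: the
within-cluster dispersion `W_k = Σ_r Σ_{i∈C_r} ‖x_i − μ_r‖²` of the data
is compared with its expectation under B = 50 reference datasets drawn
uniformly in the principal-axes-aligned (SVD-rotated) bounding box of the
data, using 10 restarts per reference fit,

    Gap(k) = mean_b log W*_kb − log W_k,
    s_k = sd_b(log W*_kb)·√(1 + 1/B),

and the smallest `k` with `Gap(k) ≥ Gap(k+1) − s_{k+1}` is chosen.
All reference draws descend from the run's seed and are reproducible.

A known behaviour of this criterion at high dimension is worth stating:
with ~400-dimensional coefficient vectors, `s_k` is very small (the
reference dispersions self-average), so the one-standard-error rule stops
only where the gap curve genuinely flattens. On the default synthetic
population the gap curve rises steeply to k = 9 — the generating number of
regions — but continues to creep upward to k = 11 before flattening,
because the two most numerous cold regions are each split along their
per-lake random-effect spread (and, for NF, along discrete ice-duration
patterns in the coefficient encoding). K-means at k = 9 recovers the
generating memberships exactly (adjusted Rand index 1.0), and the
downstream classification rule is insensitive to the extra splits; the gap
curve and `chosen_k` are both reported so users can apply their own
parsimony judgement.

Clusters are named by matching each cluster's mean seasonal statistics
(annual mean, annual range, hemisphere phase of the peak) to the reference
region table — an optimal one-to-one assignment when there are at most
nine clusters, nearest-region (duplicates allowed) otherwise.

## The classification rule

Functional PCA is applied to the seasonal profiles: the mean curve is
subtracted, and the quadrature-weighted sample covariance (uniform weights
1/n on the periodic day-of-year grid) is eigendecomposed. Eigenfunctions
are orthonormal under the quadrature inner product; by default two
components are retained (on the default population they explain ~98% of
the curve variance). Scores are quadrature inner products of the centred
curve with the eigenfunctions; user curves on other grids are linearly
interpolated (periodic, no extrapolation) onto the model grid first.

Quadratic discriminant analysis models each class as a Gaussian in score
space: class means, covariances (+ `reg_eps·I`, default 1e-6, which keeps
tiny classes non-singular), and priors proportional to class frequencies —
the sensible default given how unbalanced the regions are; a uniform-prior
variant is available by passing equal-weight labels. The posterior
probability of membership is the classification confidence, and the
second-largest posterior identifies the second-closest region.

`classify_series` chains the whole rule — ice rule, saturated spline,
seasonal profile, FPC projection, QDA posterior — and requires at least
one year (24 fortnightly observations) of data. The trained rule
serializes to one JSON document (grid, mean curve, eigenfunctions, QDA
parameters, provenance) sufficient for classification with no retraining.
`classify_location` looks a point up in a labelled 2° grid whose cells are
half-open boxes (south/west edges inclusive) with centers at odd degrees;
cells absent from the grid are reported as "no lake cell".

## Region accounting

`summarize_regions` computes per-region lake counts, percent of total,
mean seasonal temperature and range (averaged over lakes), percent of time
ice-covered, and percent of lakes with any ice. `cross_tabulate` compares
the thermal regions with any other categorical scheme via a row-normalized
contingency table. `shift_analysis` counts label transitions between two
labelings along the two warm-direction chains

    NF → NC → NT → NW → NH → TH        ST → SW → SH → TH

(TH terminal for both). A move with a positive step count is a move toward
a warmer, lower-latitude region; hypothetical cross-chain moves have no
defined step count and are reported separately as unordered changes.
Transition-matrix marginals conserve the per-period label counts by
construction.

## Numerical choices and degenerate inputs

- Saturated-spline system solved as dense symmetric-positive normal
  equations per lake (the shared design matrix is computed once per grid).
- All-ice series yield the all-zero fit rather than an error; all-identical
  clustering inputs yield k = 1 with a warning.
- Nearest-centroid ties break toward the lowest cluster index; eigenvalues
  are clipped at zero before computing explained fractions.
- Latitude 90° clamps into the northernmost grid cell; longitudes wrap
  into [−180, 180).
- Problem sizes in the test suite follow the default study conditions
  (732 lakes × 384 observations) for the end-to-end checks and much
  smaller populations for unit-level checks.

## Known limitations

- The archetype is a single harmonic: regions with genuinely
  non-sinusoidal seasonality are outside the generator's vocabulary.
- The emulator is a relaxation heuristic; its outputs are plausible
  seasonal cycles, not validated physics.
- The gap statistic's choice of k on near-noiseless, high-dimensional
  coefficient matrices can exceed the generating cluster count (see
  above); report and inspect the gap curve rather than trusting the
  selected k blindly.
- Irregular or gappy sampling is not supported; series must be complete
  fortnightly grids.
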