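# Methods

`allomove` implements a two-part analysis: a composite stress index built
from individual health assessments, and a multistream hidden Markov model
(HMM) of hourly movement and dive behaviour in which that index acts as a
per-individual covariate. The reference application is a deployment of 10
satellite-tagged narwhal; the package is written for that data shape
(hourly locations over up to 30 days, 75-s depth records, one health
assessment at capture) but is agnostic to species.

## Composite stress index

Nine markers are scored per individual: healed scars (0.5 when present),
fresh wounds unrelated to capture (2), ectoparasites (1), predators
sighted at capture (1; the dimension exists only when predators were
present), an accompanying calf for females (1), below-average body
condition (1), cortisol above the cohort upper quartile (1), DHEA-S below
the cohort lower quartile (1) and a cortisol:DHEA ratio above the cohort
upper quartile (1). Weights follow the allostatic-load convention of
equal weighting, with scars down-weighted as older, lower-grade evidence
of trauma and fresh wounds up-weighted as acute trauma.

Missing data are handled by rescaling rather than imputation: the index
is the sum of the scores of the *available* dimensions divided by their
count, so individuals assessed on three markers remain comparable with
individuals assessed on nine. An individual with no assessable dimension
cannot be scored and is excluded. Reported values are rounded to two
decimals with ties away from zero (1/8 prints as 0.13; the float default
banker's rounding would print 0.12).

Body condition is the residual of half axillary girth regressed on
standard length plus optional age-class and sex main effects; all
predictor subsets containing length are fit by OLS and the lowest-AIC
model is retained. Whether the original analysis considered interactions
is not documented; main effects only is this package's choice, and the
subset search is deliberately exhaustive rather than stepwise. Age class
splits at 300 cm standard length, with the boundary itself classed
juvenile. Hormone quartiles use the "linear" (type-7) quantile estimator
— the conventional default — and are configurable; where two blood draws
exist (start and end of handling) their arithmetic mean is thresholded.
An alternative complete-case index over any dimension subset measured for
every individual is provided for sensitivity analysis.

## Telemetry processing

Locations are assumed already regularized to a 1-h grid (the
continuous-time correlated random walk step that produces them belongs to
tracking software upstream of this package). Each track is truncated to
the window (release + 24 h, release + 30 d]: the first day absorbs
capture-related behaviour, and the cap restricts the analysis to a single
season. Step lengths are Euclidean distances (planar frame) or
great-circle distances (geographic frame); turning angles are signed
heading changes wrapped to (−π, π], with a full reversal mapping to +π.
Any hourly interval lying strictly inside a raw-fix gap longer than 3 h
has its step and turn removed — those values would be interpolation
artefacts — while dive and shore streams at those times are retained,
because they derive from the depth sensor and the raster, not from the
interpolated path, and the model tolerates partial missingness.

Depth series are zero-offset corrected by subtracting a rolling 5th
percentile of depth over a centred 2-h window, median-smoothed in a
second pass; negative corrected depths clip to 0. The window and quantile
are package defaults (the correction itself is standard but its
parameters are rarely reported); a window longer than the record falls
back to a single global offset. Dives are maximal excursions deeper than
10 m — excursions shallower than that are treated as surface behaviour.
The bottom phase is the contiguous run of samples at ≥ 0.8 × maximum
depth around the deepest sample; this depth-fraction definition replaces
the vertical-rate criteria of classical dive software because it is
simpler to specify and to test, and the fraction is configurable. Wiggles
are the summed absolute depth changes across the bottom phase. Hourly
aggregation takes the maximum of dive maxima and the sum of wiggles over
dives assigned to the hour containing their start; hours without dives
are missing, and that missingness is informative only of sampling, not
modelled.

Distance to shore comes from a gridded raster (default resolution 0.083°,
matching common marine climatology products) by bilinear interpolation
between the four surrounding cell centres; queries outside the hull of
cell centres return missing values with a warning.

## The covariate HMM

A latent first-order Markov chain over N states (N = 3 in the reference
analysis) drives five emission streams: step length, turning angle,
maximum dive depth, dive wiggles and distance to shore. Positive streams
use gamma distributions parameterized by (mean, sd); angles use von
Mises. The stress index c enters in two places:

* transitions: Γ_ij(c) = exp(β0_ij + β1_ij c) / (1 + Σ_{k≠i} exp(β0_ik +
  β1_ik c)) for j ≠ i, the multinomial-logit link with the diagonal as
  reference category (the convention of the major movement-HMM packages);
* emission means of step length, maximum depth and distance to shore:
  mean_i(c) = exp(α0_i + α1_i c). Wiggle means, angle parameters and all
  standard deviations are covariate-free; the per-stream structure is
  overridable in configuration.

The likelihood is the product over individuals of forward-algorithm
recursions computed with per-step scaling; since c is constant within an
individual, each series has a single transition matrix. A missing stream
contributes a factor of one to the emission density of its time step and
a fully missing row contributes only the transition structure, so gap
masking and dive-free hours need no imputation. Zero step lengths
(duplicate fixes) are jittered to half the smallest positive step before
gamma evaluation, with a log message, since the gamma support excludes
zero.

Fitting maximizes the log-likelihood over the unconstrained working
parameters by L-BFGS-B with finite-difference gradients, bounded at ±30
on the working scale to keep the exponential links finite. Starting
values come from per-stream quantile splits (each gamma stream's pooled
observations are cut into N quantile bins whose means and sds seed the
state parameters), angles start at zero mean with unit concentration,
transitions start mildly persistent and slopes at zero. Restarts perturb
the seed values with seeded Gaussian noise (sd 0.25, working scale); the
default is 25 restarts with relative tolerance 1e-8, and the bundled
configurations use fewer restarts with tolerance 1e-7, which on simulated
data of the deployment's size reaches the same optimum in a fraction of
the time. The initial state distribution is either an estimated shared
simplex (default) or fixed to the stationary distribution of Γ(c);
whether the original analysis estimated it is not documented, so both are
available.

The covariance of the working parameters is the inverse of a
central-finite-difference Hessian of the negative log-likelihood at the
MLE, used only when positive definite (otherwise curves are produced
without intervals, with a warning). Stationary probabilities δ(c) solve
δΓ(c) = δ, Σδ = 1 as a linear system, with an eigenvalue check rejecting
reducible or periodic chains; their 95% bands come from the delta method
through a numerical Jacobian of δ(c), clipped to [0, 1]. Decoding is by
the Viterbi algorithm with ties broken toward the lowest state index.
States are labelled after fitting by ordering on mean maximum depth: the
shallowest state is "transiting", and for N = 3 the remaining two are
"foraging_shallow" and "foraging_deep". Model comparison fits the four
covariate structures (none, transitions only, emissions only, full) and
any requested state counts, and tabulates AIC; a non-convergent cell is
flagged, not fatal.

## Synthetic data

The generators exist because the reference dataset is not publicly
deposited: they produce data with the statistical structure the analysis
assumes, plus ground truth for recovery tests.

* Tracks are drawn from the covariate HMM itself. The default truth
  parameters anchor the three states to the published stream means
  (transiting step 3832.04 m with angle concentration 1.57, maximum
  depths 46.4 / 153 / 481.5 m, wiggles 26.6 / 89.5 / 327.3 m, distances
  4.58 / 2.12 / 8.7 km). Values the reference analysis does not print
  are package choices made once: per-stream coefficients of variation
  0.4–0.7 (right-skewed but unimodal state distributions), foraging-state
  angle concentrations of 0.6 (less directed than transiting), transition
  intercepts of −2.2 (self-transition ≈ 0.82), and covariate slopes of
  1.0–1.5 into transiting and foraging-shallow with emission-mean slopes
  of |0.25–0.4| on the log scale, matching the direction of the reported
  effects. Initial states draw from the stationary distribution of the
  individual's own transition matrix. Dive streams go missing jointly
  (an hour without a dive loses both depth and wiggles).
* Health records have girth generated from a known linear model in
  length, age class and sex (half-girth noise sd 4 cm), so refitting
  recovers the generating coefficients; hormones are lognormal,
  calibrated only so cohort quartiles straddle the published cut-points
  42.3 / 5.75 / 98.2 — no fuller distributional summary of the real
  cohort exists to match.
* Depth series have scripted dives (linear descent/ascent, cosine bottom
  undulations) with additive sensor drift, and report their own
  discrete-profile ground truth for round-trip tests.
* Shore rasters hold exact distances to a parametric shoreline.

What the generators do *not* emulate: location error and its
regularization artefacts, autocorrelation within states beyond the Markov
chain, bathymetric constraints on diving, tag duty cycling, or any
dependence of health markers on subsequent behaviour other than through
the index. Passing recovery tests therefore show that the estimation
machinery is correct under the model's own assumptions at the study's
scale — not that the model is adequate for any particular real dataset.

## Test problem sizes

The recovery check uses 20 replicates of the deployment scale (10
individuals × 720 h) with the cohort's published index values as
covariates, fitting with a single data-driven start; recovery is judged
on the median absolute relative error of the 12 gamma state means
(evaluated at the cohort mean index) and the signs of the four strong
(|β1| ≥ 1) transition slopes. Model-selection behaviour uses a smaller 6
× 240 design, 10 replicates per scenario. Interval calibration uses 200
replicates of a two-state, single-stream design (12 individuals × 120 h,
stationary initial law, optimizer started at the generating values to
keep every replicate in the same labelling mode), pooling coverage
indicators across three covariate values and both states. These sizes
are the package's trade-off between Monte-Carlo resolution and a test
suite that runs in minutes.

## Known limitations

* The confidence bands ignore parameter non-identifiability near label
  switching; they are meaningful only at a well-separated optimum.
* No random effects on transitions and no multiple imputation of health
  markers — with 10 individuals both were out of reach for the reference
  analysis too, and larger cohorts would want them.
* The body-condition model is cross-sectional; residual condition
  conflates body shape and measurement conditions.
* The sd of covariate-bearing streams is state-constant by construction;
  heteroscedastic responses to stress would be absorbed into the mean.
* The dive detector's fixed bottom fraction can understate wiggles for
  strongly skewed dive profiles.
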