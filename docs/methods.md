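# Methods

`pengmove` re-implements, as a tested pipeline, the movement and behavior
analysis applied to satellite-tracked juvenile and non-breeding king
penguins dispersing from the Crozet Archipelago: Argos track filtering,
net-squared-displacement (NSD) segmentation into latent movement states,
behavioral-mode clustering of duty-cycled dive records, penalized-spline
binomial habitat models with individual random effects, and orientation
analysis relative to wind and ocean currents. Because the original field
data are not publicly deposited, the package ships a synthetic study
generator whose outputs have the statistical structure every downstream
stage assumes, so the whole pipeline is exercisable and testable offline.

## Geometry

The Earth is a sphere of radius 6371.0 km. Distances are haversine
great-circle distances, matching the spherical conventions of the R
tracking packages this pipeline mirrors; headings are initial great-circle
bearings, degrees clockwise from true north. The habitat model's spatial
coordinates use the spherical Lambert azimuthal equal-area projection
(Snyder's forward/inverse equations) centered on the colony (46.43°S,
51.86°E). Longitudes are stored in [-180, 180); any sequence operation
(daily averaging, interpolation) first unwraps longitude so meridian
crossings are handled along the short arc.

Track re-interpolation for orientation analysis is linear in
(latitude, unwrapped longitude) on a regular 12-h grid anchored at the
first fix. At ~1 m/s travel speeds the difference from interpolating in
projected coordinates is negligible. No points are produced inside
observation gaps longer than 48 h (configurable); tags routinely fall
silent for days and inventing positions across such gaps would bias
headings.

## Speed filter

Argos fixes carry occasional extreme errors. Fixes implying travel above
14 km/h (the ceiling used for this species) are removed iteratively,
McConnell-style: each interior fix is scored by the root-mean-square of
speeds to up to two previous and two subsequent retained fixes, and while
any consecutive pair involving an interior fix violates the ceiling, the
worst-scoring implicated fix is removed. First and last fixes are exempt —
a terminal fix has one-sided evidence only — and any residual terminal
violation is reported rather than acted on. Ties break toward the earlier
fix, so the filter is deterministic. A final reinsertion pass puts back
any removed fix that is compliant with its retained neighbors: a clean fix
sandwiched between two spikes can transiently carry the worst RMS score,
and reinsertion restores it once the true spikes are gone. The filter is
idempotent, and on small tracks it reproduces the unique
minimum-cardinality removal when one exists (both are tested). The same 14 km/h ceiling is applied to
dive-to-dive travel speeds, where two dives minutes apart mapped to
different jittered fixes can otherwise imply absurd speeds.

## NSD segmentation

NSD is the squared great-circle distance between each average daily
location and the first location of the trip. Each individual's daily NSD
series is segmented with a 3-state hidden Markov model with Gaussian
emissions on square-root-transformed NSD (NSD is km² with a heavy right
tail; `log1p` is available as an alternative transform). Parameters are
estimated by EM (Baum–Welch, via hmmlearn) with 10 random restarts, best
likelihood kept, and the state path is decoded with Viterbi. States are
relabeled deterministically: of the two lower-variance (encamped) states
the one with the smaller emission mean is state 1 (summer residency), the
larger is state 2 (winter residency); the highest-variance state is state
3 (transit). A maximum-likelihood HMM is substituted for the Bayesian
latent-state formulation used in the original workflow because only the
decoded states are consumed downstream, not posteriors or credible
intervals. Constant series trigger a flagged single-state fallback.
Individuals tracked for fewer than 120 days (configurable) are excluded
from segmentation: a deployment much shorter than the seasonal cycle
cannot express all three phases.

The winter range is the set of 1°×1° cells visited during state 2, with
day counts per cell. Environmental variability inside the winter range is
summarized by a column-standardized PCA (SVD) of the covariates sampled at
state-2 daily locations; constant columns are dropped with a warning.

## Dive modes

Dive summaries arrive on a 1-day-ON / 2-days-OFF duty cycle. Each dive is
matched to the nearest-in-time filtered fix within ±90 min (else dropped);
travel speed is the distance between consecutive dive locations of the
same recording day divided by the difference of dive initiation times.
Hourly means of maximum depth, dive duration, post-dive surface interval
and travel speed form the clustering records.

Records are standardized (the four variables mix meters, seconds and km/h;
unscaled L1 distances would be depth-dominated; a raw-scale option is
retained) and clustered with Manhattan distance and UPGMA linkage,
separately per stage. Cutting an average-linkage tree at exactly k = 3
reliably wastes cluster slots on outlier singletons, so the default adds
the k-means consolidation pass of the HCPC workflow this stage mirrors:
the tree is cut at several depths (k, k+4, …, k+20), the centroids of the
k largest clusters at each depth seed a k-means refinement, and the
solution with the lowest within-cluster dispersion is kept. The procedure
is deterministic for a fixed input order and invariant to row permutation
up to label renaming. When records are plentiful the O(n²) tree is built
on an evenly spaced subsample (default cap 6000) and consolidation assigns
every record. A plain cut (`consolidate=False`) is retained.

The cluster with the highest mean travel speed is labeled 'traveling', the
others 'foraging'; if the traveling cluster is also the deepest, the
labeling is flagged for review rather than silently accepted.

## Habitat model

The probability that an hourly record is foraging (1) rather than
traveling (0) is modeled on the logit scale as a sum of: penalized cubic
B-spline smooths of environmental covariates (default basis dimension 10,
quantile-spaced knots, second-difference coefficient penalty plus a small
ridge so a term can shrink to exactly zero — the "shrinkage" property); an
optional 5×5 tensor-product smooth of the projected coordinates; treatment-
coded factors (year, stage, season — austral seasons by month: Dec–Feb
summer, Mar–May autumn, Jun–Aug winter, Sep–Nov spring, configurable); and
a per-individual random intercept implemented as a ridge-penalized
coefficient block (the standard random-effect-as-smooth equivalence, with
variance 1/λ).

Fitting is penalized IRLS (Newton with step halving, so the penalized
log-likelihood never decreases). Smoothing parameters — one per smooth,
one for the tensor, one for the random-intercept precision — are chosen by
coordinate descent over log-spaced grids (defaults: half-decade steps over
10^-2..10^4 for smooths, quarter-decade for the random intercept, two
sweeps), maximizing a Laplace approximation to the marginal likelihood.
This honors the restricted-likelihood spirit of the original analysis
without claiming numerical equivalence to mgcv's REML; a test nevertheless
checks agreement of fitted probabilities with mgcv on shared data.
Effective degrees of freedom are per-block traces of the influence matrix;
model selection uses conditional AIC = -2 logLik + 2·edf (the
conditional-vs-marginal AIC debate is acknowledged; the conditional form is
used consistently, so comparisons are internally coherent). The dredge
fits every subset of candidate environmental smooths (factors always
included; ≤12 candidates), ranks by AIC, and flags selection as ambiguous
when the runner-up is within 2 AIC units. Predictions set the random
effect to its population mean and flag covariates outside the training
range (inputs are clipped to it).

Environmental covariates are sampled at record locations by bilinear
interpolation in space at the nearest time slice; records outside the grid
are excluded with a logged count.

## Orientation

Tracks are re-interpolated at 12-h intervals; each segment's heading is
differenced against the direction the medium flows toward, sampled at the
segment start (a config switch samples midpoints instead). Wind and
current U/V components are assumed to point in the direction of flow (the
model-output convention); inputs using the meteorological "from" convention
must declare it, and the package applies the 180° rotation — silent
convention mixing is the classic failure mode of this analysis. The
angular difference is binned: [315°, 360°) ∪ [0°, 45°] similar
(downstream), [135°, 225°] against (upstream), the rest cross. Boundary
membership follows the closed bins as printed; the choice is measure-zero.
For isotropic headings the bins cover 25/25/50% of the circle, which is
the tested null.

Class-proportion tables compute per-individual proportions first and then
mean ± SD across individuals, so the SD reflects inter-individual spread;
cells with one individual report no SD and are flagged. Seasonal/stage
differences in the upstream-vs-downstream split (cross excluded) are
tested with a binomial random-intercept GLMM fitted by maximum likelihood
with adaptive Gauss–Hermite quadrature (≥9 nodes, mode-and-curvature
adapted per individual; cross-checked against brute-force quadrature and
lme4). Cells enter as a cell-mean parameterization so pairwise contrasts
are coefficient differences; p-values are Bonferroni-adjusted and
summarized as compact letters (cells sharing a letter are not
significantly different). The productivity analysis models upstream choice
as smooth functions of CHLA at the segment start (t) and end (t+1),
reusing the habitat fitting core.

## Synthetic study generator

The generator emulates the study conditions: 17 juveniles departing around
1 December and 6 non-breeders around 1 March, alternating over two field
seasons (so the year factor is identifiable), tracked for ~206/220 ± 30
days. Tracks are correlated random walks from the colony with three
planted phases — encampment (mean step speed 1.8 km/h, anchored within
~250 km), a ~45-day directed transit toward 235° (3.6 km/h, concentrated
headings), and a second encampment — so daily NSD shows plateau–ramp–
plateau. Fix times use exponential inter-fix gaps with a 1-h floor, tuned
to 14.5 fixes/day (the floor keeps jitter-implied speeds of clean fixes
below the filter ceiling, so planted outliers are the only violations).
Argos error is isotropic Gaussian jitter (SD 1.5 km, truncated at 2 SD);
with probability 0.05 a fix is displaced 150 km and labeled as an outlier.
Quality-class error ellipses are not modeled: the filter acts on speed
only.

Dives occur only on ON days, ~55 per recording day, with depths above the
2-m recording threshold; per-hour behavioral regimes follow a 2-state
Markov chain whose stationary traveling fraction is ~0.75 during transit
and ~0.18 while encamped (≈30% traveling overall, with ~6–12-h dwell
times). Traveling hours draw dive parameters from the published cluster-1
distributions (truncated normals); foraging hours from the cluster-2/3
mixture. Environmental fields are smooth analytic surfaces on regular
grids (default 2°, 3-day step): a meridional SST gradient with seasonal
cycle and noise, winter-deepening MLD, sea ice south of ~58°S, CHLA as a
positive sum of Gaussian patches, a weak eastward mean current (0.11 m/s)
with smooth meanders, and prevailing westerlies (~8 m/s) with synoptic
variability.

What the generator does not emulate — and hence what passing tests do not
show about real data: per-quality-class Argos error structure, real ocean
circulation (fronts, eddies) and its coupling to bird behavior, dive-shape
detail, tag failure and transmission dropout patterns, and any coupling
between dive-derived travel speed and the published cluster speeds in the
end-to-end bundle (there, hourly speed comes from track geometry, so the
full-pipeline mode labels are noisier than the direct-mixture clustering
test; the published speed distributions are planted only in the
direct-mixture simulation used by the clustering recovery checks).

## Numerical choices and problem sizes

Testing and the acceptance script use reduced but structurally complete
problem sizes chosen as this package's own defaults: full-size synthetic
bundles (23 individuals, ~200 days) for the pipeline checks; n = 5000
records for mixture-clustering and habitat recovery; 20–60 replicates for
selection-consistency, error-control and power simulations, with coarse
smoothing grids (decade steps, one sweep) in replicated fits and the finer
default grids in single fits. All randomness flows from explicit seeds;
rerunning any stage with the same seed reproduces outputs byte for byte.

Known limitations: the Laplace-ML smoothing criterion can retain ~1–2
effective df of spurious wiggle on null terms (mgcv's REML shows the same
behavior); the conditional-AIC dredge can admit a near-zero-edf extra term
alongside the true ones; the random-intercept SD estimate is grid-quantized
(quarter-decade resolution); and the GLMM letters display uses a greedy
insert-and-absorb algorithm, adequate for the handful of stage-season
cells it summarizes.
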