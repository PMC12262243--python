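# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of the package, stage by stage.

## Geometry and relative density

Patches are circles by default (pipetted droplets are circular); polygon
boundaries are accepted for generality and evaluated through shapely. The
signed distance to the nearest patch edge is positive inside a patch; the
"nearest" patch is the one with the largest signed distance (the containing
patch if any, else the closest edge), ties broken to the lowest patch id.

Relative density is estimated from radial fluorescence-intensity profiles:
the profile peak is the intensity maximum; the border is the curvature
maximum (second difference after a 3-bin moving average) outside the peak —
the outer kink where the falling edge meets the background plateau, with ties
across the kink resolved to the outermost bin. Border amplitude is the
peak-to-border intensity drop; dividing by exposure time gives the relative
border amplitude, fit per condition against growth time by OLS. The scale is
pinned so that a 0.5 µL OD600=10 patch grown 1 h has relative density 10.
The exact curvature estimator used upstream of this package is not specified
anywhere authoritative; only the border/peak/amplitude semantics matter
downstream, and the smoothing window is exposed as a parameter.

## Encounter detection

Three calibrated thresholds, all in mm: an encounter is an interval with the
midpoint within **0.46024** of a patch edge (the median head-to-midpoint
distance when the head first touches the edge); intervals whose midpoint
never came within **0.28758** of the edge are near misses and are dropped;
consecutive same-patch intervals whose intervening "off-patch" excursion has
distance SD below **0.22221** are merged (outstretched feeding postures, not
true leaving events). Merging is transitive left-to-right; a single-frame gap
has zero variability by definition and always merges. Distances are evaluated
per frame with no sub-frame interpolation (tracking runs at 3–8 fps, which
bounds entry/exit precision at one frame). An interval's patch identity is
the nearest patch at the frame of deepest approach. Worms with more than 25%
missing frames are excluded. Intervals abutting the recording bounds are
flagged left-/right-censored.

`calibrate_thresholds` recovers all three numbers from high-resolution tracks
with head positions: median head-to-midpoint distance over head-on-edge
frames; magnitude of the 1st percentile of signed midpoint-to-edge distance
over head-on-patch frames; and the posterior-0.5 crossing of a two-component
1-D Gaussian mixture on off-patch distance SDs (an error is raised when those
SDs are not bimodal, since the merge rule is then unidentified).

## Kinematic features

Velocity is the central-difference speed of the midpoint, smoothed by a 1 s
moving average (the estimator upstream is unstated; the window is a
parameter, and velocity-dependent tests carry tolerances sized to it). Entry
deceleration is the OLS slope of velocity over [entry − 1.5 s, entry + 6.5 s]
— unavailable (NaN) when the window is truncated, which marks the encounter
for marginalization. Max Δ velocity is the peak velocity in the 10 s before
entry minus the minimum on-patch velocity, floored at 0. Log features use
natural log with durations floored at one frame.

## Bimodality (Silverman's test)

Feature matrices are mean-centered and projected onto PC1 (principal
components and principal curves coincide for the one-mode null). The critical
bandwidth h\* is the smallest Gaussian-KDE bandwidth with ≤ 1 mode, found by
bisection to 1e-4·σ. The smoothed bootstrap resamples with replacement and
rescales, z̃ = (z\* + h\*ε)/√(1 + h\*²/σ²) with ε ~ N(0,1), preserving the
sample variance; p is the fraction of 2000 (default) replicate h\* values at
least as large as the observed one.

Numerics: mode counting bins the sample onto a 2048-point grid padded by 8
bandwidths and smooths in the Fourier domain — one FFT multiply per
bandwidth, O(grid log grid) independent of n. Modes are counted only inside
the data range ± 3h (a Gaussian KDE cannot have modes beyond that, and the
circular FFT wraps the far tails); derivative sign changes below 1e-10 of the
density maximum are ignored as FFT ripple. The binned counter matches an
exact kernel-sum oracle across bandwidths in the tests; at bandwidths below
the bin width distinct points can merge, which only matters far below any
realistic critical bandwidth.

## State classification

**Explore/exploit.** Two-component full-covariance GMM on (log duration, log
mean on-patch velocity) with ridge α·I on the component covariances. α is
chosen on a grid by 5-fold cross-validation repeated 10 times (default),
minimizing the mean held-out posterior variance Σ p(1−p) — the count of
replicates used for this tuning is a package choice; the criterion itself is
the method's. The exploit component is the one with the larger mean log
duration. A degenerate EM fit at small α falls back to the next larger α.

**Sensing/non-responding.** Semi-supervised QDA on (min velocity,
deceleration, max Δ velocity). Per replicate (1000 by default): bacteria-free
(density-0) encounters are negatives; exploit encounters are drawn positive
y ~ Bern(p(y=1|z)); QDA is fit on the labeled set and grown by self-training
— unlabeled points with posterior beyond 0.95 either way are adopted — until
assignments stabilize or 50 iterations (the iteration schedule is a package
choice; the labeling assumptions are the method's). p(sensed) is the
arithmetic mean over replicates. Replicates with no sampled positive are
redrawn.

**Censored entries.** When the recording starts with the animal already on
patch, deceleration and max Δ velocity are biased toward zero, so sensing is
predicted from the minimum on-patch velocity alone by marginalizing the QDA
conditional over the unseen features: p(v=1|s) = ∬ p(v=1|s,t,u) p(t,u|s) dt du,
with p(t,u|s) a Gaussian product-kernel KDE (rule-of-thumb bandwidths per
dimension, mixture weights from the s-kernel) and the double integral done by
adaptive quadrature over the reference range ± 5 bandwidths, normalized by the
analytic truncated KDE mass. Values of s outside the reference support are
clamped to the nearest support point with a warning.

**Composition.** p_search = 1 − p_sensed, p_sample = p_sensed(1 − p_exploit),
p_exploit = p_sensed·p_exploit; the search term is computed as the exact
floating-point complement of the other two so the triple sums to one exactly.
Residual near misses — midpoint never inside the patch proper and
p(sensed) < 0.05 — are excluded downstream.

## Exploitation model

Covariates per sensed encounter: ρ (densities) in natural log, τ (times) in
hours — both unit choices are package decisions, exposed in the code, and
rescale the coefficients accordingly. τ_s at encounter k is the time since
the end of the last exploited encounter minus on-patch time of retained
encounters in between; removed (non-sensed) encounters count as off-patch
time by construction. ρ_h and ρ_e initialize at the acclimation-plate density
(default relative density 200, the ~20× denser pre-assay lawn); ρ_e stays
there until the first exploit. The response is soft, but the τ_s reset and
ρ_e update need discrete exploit events: an encounter counts as exploited for
bookkeeping when q > 0.5 (the mixture posteriors are near 0/1 by
construction, so this is nearly equivalent to sampling the label). Density-0
encounters never enter the fit; supplying one raises an error.

The fit is Newton/IRLS on the concave soft-label objective with backtracking,
convergence at gradient norm < 1e-8; the ridge penalty (λ ≥ 0) excludes the
intercept. Perfect separation at λ = 0 is detected (diverging coefficients, or
convergence with every probability saturated) and raised as an error advising
λ > 0. Replicates: encounter sampling (default 100) × worm bootstrap (default
500); the full product is used, and worm multiplicity enters as frequency
weights, which is likelihood-identical to row duplication and much faster.
Failed replicate fits are excluded and counted; if more than 1% fail the run
aborts advising λ > 0. Empirical p-values are floored at 2/(n_replicates+1).
Ridge λ is tuned by cross-validated held-out soft log-likelihood with folds
grouped by worm, so one animal's encounters never straddle the split. Strain
comparisons use Z = (μ_mutant − μ_ref)/√(σ²_mutant + σ²_ref), left-tailed for
the density coefficients (is density sensitivity reduced?), two-tailed
otherwise, BH-corrected across coefficients.

## Residence permutation test

Null placements re-draw each patch uniformly over the feasible disc in random
order, rejecting patch–patch and patch–arena overlaps (10⁴ proposals per
patch before declaring the arena over-packed); radii and densities are
preserved exactly. A pure rotate-and-perturb scheme would not make a single
patch's null position uniform over the feasible disc, which is the distribution
the test's null requires. Per time bin, observed on/off-patch counts are
compared with counts pooled over permutations by a one-tailed Fisher's exact
test, BH-corrected across bins. The observed margin counts **one sample per
worm per bin** (the frame nearest the bin center): consecutive frames are
strongly autocorrelated, and counting each frame as an independent Bernoulli
trial makes the test wildly anti-conservative. Full-frame fractions are still
reported for display. This makes the test conservative at small worm counts —
a deliberate trade.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study's statistical structure: a 30 mm circular
arena (9 mm single-patch assays are a parameter change) with an isometric
grid of 0.9 mm patches; relative densities {1, 5, 10} by default (the
multi-density assay — the decision model is unidentifiable at a single
density, where ρ_k is collinear with the intercept); 3 fps tracks; off-patch
roaming at 200 µm/s as a persistent random walk (Gaussian heading increments,
reflecting arena wall — no turning statistics are claimed beyond the speed
regimes, and nothing downstream depends on them); entry decelerations of
~19.5 µm/s² toward on-patch speeds of 110 (sample) / 50 (exploit) µm/s;
sample dwells under 2 min and exploit dwells over 2 min. Decision sequences
draw exploits from Bern(logistic(β·x)) with default
β = (−1, 1.5, 0.5, −0.5, −0.8) — moderate, sign-definite effects for every
covariate at the covariate ranges the sequences produce — with ~41% of
encounters truly sensed (mirroring the reduction from all detected encounters
to sensed encounters under encounter sampling), sensing posteriors of
0.95/0.05 for sensed/non-sensed encounters, exponential inter-encounter
travel times (mean 5 min), and 15 encounters per worm. All randomness flows
from one seed via per-worm sub-streams; identical seeds give byte-identical
outputs.

Not emulated: body posture (the generator has no head, so detection-threshold
*calibration* is exercised on purpose-built fixtures instead), bacterial
growth during the assay, density-dependent slow-down magnitudes, and any
worm–worm interaction. Passing tests therefore show that the statistical
machinery is correct under the stated kinematic regimes — not that those
regimes exhaust real worm behavior.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use sizes chosen to make
Monte Carlo error small relative to the tolerances they check: 50 datasets of
n=500 for the objective-equivalence check (agreement ≤ 1e-6); one cohort of
~2500 sensed encounters with a 100×100 replicate product for sign recovery,
plus 30–40 cohorts at 20×20 for interval coverage (percentile tails need a
few hundred replicates to be stable); 200 tracks against the brute-force
detection oracle; 200 null and 60 mixture simulations (n=500, 100 bootstraps)
for Silverman calibration and power; 10⁵ simulations for the geometric
first-exploitation law; 100 patch-blind cohorts for residence-test
calibration; 60 datasets of n=3000 for BIC preference and 120 null fits for
LRT calibration.

## Known limitations

- Finite-sample logistic MLE bias is visible at high-leverage covariate
  configurations (the acclimation initialization puts early encounters at
  ln 200 ≈ 5.3 while assay densities sit in [0, 2.3]); percentile bootstrap
  intervals inherit it, so per-coefficient coverage can dip below nominal for
  the density coefficient even while overall coverage stays near 95%.
- Encounter sampling mixes a few percent of truly non-sensed (never-exploit)
  encounters into the fit and drops a few percent of real ones; coefficient
  distributions are correspondingly widened and mildly shifted. This is the
  price of propagating classification uncertainty rather than conditioning on
  hard labels.
- The residence Fisher test treats worms as exchangeable and bins as
  independent tests under BH; with very few worms it is conservative.
- `classify_duration_gmm`'s censored refit simply excludes left-censored
  encounters; it does not model truncation explicitly.
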