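# Methods

This note documents the models, parameters, and numerical choices behind
`contourpass`. The package simulates and analyzes a contour-in-noise
detection study with two groups of observers and three measurement
channels: yes/no responses, reaction times, and per-trial gaze positions.

## Stimulus model

Gabor elements sit on a regular hexagonal grid of 39 columns x 25 rows at
1.044 deg spacing (975 elements) on a 40 x 22.5 deg screen sampled at
48 px/deg (1920 x 1080). Each element is an odd-symmetric (sine-phase)
Gabor: 5.75 cpd carrier, 0.087 deg Gaussian envelope truncated at a
0.522 deg diameter (3 sigma), 75% Michelson contrast on a 0.5 background.
Sine phase makes every patch exactly zero-mean, so the rendered image mean
equals the background; overlapping truncation windows are summed and
clipped, with clipping logged.

Coordinates are degrees of visual angle, origin at the screen center, x
rightward, y upward. Orientation is the stripe axis in degrees from
horizontal, counter-clockwise positive, wrapped to (-90, 90].

The target is a straight 12-element contour along the 60-degree lattice
direction. A geometric subtlety: with 25 rows and the bounding box
centered on the screen, one grid row lies exactly on the horizontal
midline, so a 12-element run along 60 deg cannot straddle the exact
center; `select_contour_path` returns the run whose midpoint is closest to
the center (it lands at (0, +/- sqrt(3) x 1.044 / 4) ~ 0.45 deg). The
39-column grid with half-row offsets is 40.19 deg wide, overhanging the
screen horizontally by ~0.1 deg on each side; rendering clips at the image
border.

External noise is orientation jitter: at level delta, exactly six contour
elements are tilted to 60 + delta and six to 60 - delta (random
permutation). This balanced assignment keeps the unwrapped contour mean at
exactly 60 deg and sets the contour orientation SD to exactly delta.
Background elements (and all elements on contour-absent trials) draw
independent uniform orientations on (-90, 90], whose SD is
180 / sqrt(12) ~ 52 deg.

A session comprises eight 60-trial blocks (30 contour-present / 30
contour-absent, randomly interleaved): the six noise levels
{0, 10, 20, 30, 45, 60} deg in random order (pass 1), then exact
stimulus-by-stimulus replicas of the 10 and 45 deg blocks (pass 2), always
last. A single master seed drives everything through spawned
`numpy.random.SeedSequence` children, so any trial is independently
reproducible and repeated blocks are byte-identical.

## Generative observer

The observer works on element orientations, never pixels — sufficient for
every statistic the pipeline computes and orders of magnitude cheaper.
Its template covers the 12 contour positions (weight 1) and their 28
hex-adjacent background positions (weight `template_weight_bg`).

The default decision channel ("channel") sums two components:

* **Orientation evidence.** Two circular-Gaussian orientation channels
  centered on the jitter orientations 60 +/- delta (tuning SD
  `channel_bandwidth`, default 30 deg); each template element contributes
  its best channel response. The blocked design holds delta fixed and
  known within a block, so a per-block template pair is a reasonable model
  of an adapted observer. Every balanced-jitter contour element matches
  one channel exactly, contributing 1.
* **Collinearity (good continuation).** The mean axial alignment
  `mean cos 2(theta_i - theta_{i+1})` over the 11 consecutive contour
  positions, weighted by `collinearity_weight` (default 0.2). Its value on
  a signal trial depends on the random +/- assignment (same-sign neighbor
  pairs contribute 1, opposite-sign pairs cos 4 delta), which makes it a
  genuine stimulus-driven noise source: frozen across the two passes of a
  repeated block, with variance growing with delta. This is the external
  variability the double-pass logic requires; with a plain cosine template
  and no background weight, the signal statistic would be deterministic
  per level and the paradigm would degenerate.

The decision variable is s + eps with eps ~ N(0, sigma_i^2) and
`sigma_i = sqrt(sigma_add^2 + (k_mult * delta)^2)` — additive plus
stimulus-dependent internal noise. The response is "yes" iff s + eps
exceeds the criterion; by default the criterion sits midway between the
closed-form expected signal and noise statistics of the level (the
background channel mean is a cached numeric tuning-curve integral). With
probability `lapse` the response is replaced by a fair coin.

Two alternative channels are kept for analysis of degenerate regimes: the
plain cosine statistic `sum w cos 2(theta - 60) / sum w` ("cosine", the
recorded per-trial diagnostic) and a raw two-template max-cosine rule
("matched"). The cosine observer is at exact chance at delta = 45 (the
balanced +/-45 jitter makes the class means coincide: cos 90 = 0) and
below chance at 60 with an unbiased criterion; its accuracy declines
monotonically with delta, which the suite verifies. The default channel
observer stays above chance at every level; its accuracy declines through
45 deg and is approximately flat (slightly non-monotone) between 45 and
60, because the two jitter orientations at 60 deg are more discriminable
from the background than the orthogonal pair at 45 deg — a property of
any two-template matcher, not a bug.

## Default cohort

Two groups, 24 (ASD-like) and 32 (TD-like) subjects. Group parameter
means encode the study's interpretation of its findings:

| parameter | TD | ASD | role |
|---|---|---|---|
| `sigma_add` | 0.030 | 0.035 | additive internal noise (similar across groups) |
| `k_mult` (per deg) | 0.0016 | 0.0038 | stimulus-dependent internal noise (main group deficit) |
| `template_weight_bg` | 0.60 | 0.75 | noisier perceptual template |
| `lapse` | 0.010 | 0.035 | attention lapses |
| `rt_shift` (s) | 0.45 | 0.62 | group RT offset |
| `gaze_sigma0` (deg) | 0.55 | 0.85 | baseline gaze dispersion (minor axis) |
| `gaze_noise_slope` (per deg) | 0.010 | 0.016 | noise-dependent gaze spread |
| `gaze_outlier_rate` | 0.055 | 0.14 | tracking-loss mixture |
| IQ mean (SD) | 102 (13) | 84 (17) | group descriptives |

Magnitudes were fixed once at design time from closed-form accuracy
predictions and pilot runs so that: group accuracy spans roughly 0.99 to
0.60 across levels with the ASD-like group lower at every level; the
agreement/accuracy slopes are similar at 10 deg but clearly lower for the
ASD-like group at 45 deg (larger `k_mult` dominating at high external
noise); tracking loss at sigma 20 deg reproduces ~10% vs ~4% off-screen
gaze exclusion; and the between-subject spread of mean gaze positions
(`gaze_center_sd` 0.08 vs 0.04 deg plus retained-outlier contamination)
yields median pairwise distances near 0.2 vs 0.12 deg.

Subject-level parameters are log-normal around the group means with a
shared "noisiness" latent u ~ N(0, 1) (loading 0.6) that also loads
negatively on IQ (-0.5) and positively on gaze dispersion. This single
latent plants the IQ-accuracy, gaze-area-accuracy and gaze-area-RT
correlations the analyses look for. Ages are uniform on 8-16 years.

Reaction times are shifted gamma:
`rt_shift + Gamma(rt_shape, rt_scale * (1 + rt_noise_slope * delta))`.
Gaze is one mean position per trial: bivariate normal around the
subject's habitual offset, horizontal SD `gaze_aspect` (1.6) times the
vertical, both scaled by `(1 + gaze_noise_slope * delta)`, mixed with an
isotropic N(0, 20^2) tracking-loss component. RT and gaze parameters are
stand-ins with the study's qualitative structure; they are not estimates
of any real population.

## Double-pass analysis

Per subject and repeated level, pa = percent agreement between the two
passes and pc = percent correct pooled over both. The comparative index
`pc = m log10(pa/100) + 100` is fitted by least squares through the fixed
point (100, 100): with x = log10(pa/100), y = pc - 100, m = sum(xy) /
sum(x^2), SE from the one-parameter regression (n - 1 df). On synthetic
cohorts the fitted slopes are two orders of magnitude larger than
published values of this index, because realistic (pa, pc) pairs sit far
from the relation's (100, 100) anchor; the slope is therefore treated
purely as a comparative index between groups and levels (pooled
participant points per group x level, compared with a Welch t test on the
fitted SEs), and the quantitative workhorse is the model-based estimator.

The linear-amplifier model (LAM) fixes the external noise SD at 1 and has
signal offset d, internal/external ratio r, and criterion gamma. The two
passes share the frozen external draw, so the pass-wise decision
variables correlate at rho = 1/(1+r^2), and

* P(yes | class) = Phi((mu_c - gamma) / sqrt(1 + r^2)),
* P(both yes) = Phi2(a, a; rho), evaluated exactly via Owen's T
  (`Phi2(a, a; rho) = Phi(a) - 2 T(a, sqrt((1-rho)/(1+rho)))`).

With the unbiased criterion gamma = d/2, pc fixes h = (d/2)/sqrt(1+r^2)
= Phi^-1(pc), and pa is solved for rho by bracketed root finding
(brentq, |f| < 1e-12). Infeasible pairs — pc outside (50, 100), or pa
below the independence floor `Phi2(h,h;0) + Phi2(-h,-h;0)` — raise a
feasibility error naming the violated bound; pa = 100 returns r = 0. At
the study's repeated-trial budget (120 stimulus pairs per participant)
the estimator's median absolute error in r is about 0.15 for true r in
[0.5, 1.5] at its most informative operating point (pc ~ 65-70%), and
grows steeply for r near 1.5; single-point estimates at this budget
should be treated as noisy.

## Behavioral statistics

RT outliers are excluded outside [0.25, 4.0] s, boundary values retained
("less than" / "more than" read strictly); exclusions are logged per
subject and the filter is idempotent. SDT categorization
(hit/miss/false-alarm/correct-rejection) is exhaustive per subject x
level; percentages are relative to class trial counts; d' with log-linear
correction is available but off by default. SDT percentages are computed
on unfiltered trials (the RT filter applies to RT analyses only).

The Bayesian bootstrap draws flat Dirichlet weights over observations
(default 4000 draws) and evaluates the weighted mean or weighted median;
intervals are the 2.5/97.5 posterior percentiles, and group comparisons
report the paired-draw probability that one group exceeds the other.
Group-level figures bootstrap subject-level summaries (one value per
subject), not trials. Pearson correlations report r, a Fisher-z 95% CI,
and a t-test p on n - 2 df.

## Gaze point-pattern analysis

Gaze positions are a marked point pattern on the 40 x 22.5 deg window
(area 900 deg^2); positions outside are excluded first (boundary
inclusive), with the excluded fraction reported per group.

* **Quadrat test**: 5 x 5 equal-area quadrats (df 24), chi-square against
  the uniform expectation; a warning is logged when expected counts drop
  below 5. Type-I error calibration is verified by simulation.
* **Inhomogeneous Poisson models**: log-quadratic trend
  `log lambda = b0 + b1 x + b2 y + b3 x^2 + b4 y^2 + b5 xy` plus
  categorical mark covariates (stimulus class, group, noise level) and
  optional covariate x spatial interactions. Fitting uses the
  Berman-Turner quadrature device: a 64 x 36 dummy grid per stratum with
  counting weights (each tile's area split over the data + dummy points
  in it), reducing the point-process likelihood to a weighted Poisson
  regression solved by IRLS with step halving. The linear predictor is
  clipped at +/-35 during iteration: tight gaze clouds legitimately push
  log lambda below -700 at the window edges, which would underflow.
  Wald SEs come from the Fisher information. The score equation makes the
  fitted intensity integrate to the observed count (checked to 0.1%).
  For likelihood-ratio tests the null must be fitted on the same
  stratified quadrature as the full model (`strata=` argument); fitting
  the null on a pooled unstratified device would compare incomparable
  likelihoods, which the nesting check rejects.
* **Inhomogeneous K**: border-corrected estimator — for each r, centers
  at least r from the boundary, K(r) = mean over centers of
  `sum_{j != i, d <= r} 1 / lambda(x_j)`; unbiased for pi r^2 under
  Poisson. Envelopes are pointwise min/max over simulations of the fitted
  model by thinning. The full-cohort K analysis subsamples to 1500 points
  per group (the estimator is O(n^2)); envelopes with 19 simulations give
  a 10% pointwise band, used graphically.
* **Ellipses and dispersion**: variance ellipses from the sample
  covariance eigendecomposition (95% area `pi * 5.991 * sqrt(l1 l2)`,
  collinear clouds flagged degenerate); elongation and group variance
  comparisons by two-sided F tests; per-subject dispersion
  `sqrt(var_x + var_y)` per level, compared across groups by the
  bootstrap. "Gaze area" per subject is the 95% variance-ellipse area
  pooled over trials (convex hull available as an option), correlated
  with mean accuracy, median RT, and IQ.

Trial-level points enter the patterns directly (one mean gaze point per
trial); subject identity is a mark, and analyses that need per-subject
aggregation (pairwise distances of mean positions, dispersion, areas)
aggregate explicitly.

## What the synthetic cohort does and does not show

The generator reproduces the statistical *structure* the analyses assume:
blocked double-pass design, frozen repeated stimuli, group differences in
stimulus-dependent internal noise and gaze dispersion, planted
performance-IQ-gaze couplings, heavy-tailed tracking loss. It does not
emulate saccade dynamics or fixation events, realistic RT process models,
pixel-level decision making, criterion drift across sessions, or
learning. Passing end-to-end tests therefore demonstrates that the
pipeline detects effects of the planted kind at realistic sizes — not
that the specific parameter values describe any real population.

## Problem sizes in the test suite

The shipped tests run the full default cohort (56 subjects x 480 trials)
once and reuse it; Monte-Carlo oracles use 10^6 trials per LAM grid cell,
1000 simulations for quadrat calibration, 100 replicates for ppm
coefficient coverage, and 10^5 draws for ellipse coverage. These sizes
keep each check's own Monte-Carlo error well below the tolerance it
asserts.
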