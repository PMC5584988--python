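# Methods

## Coordinate frame and data model

All depths are signed millimetres with the gel surface as datum (`z = 0`,
positive up). The default chamber is a 12 mm agarose column under a 2 mm air
chamber, 3 mm wide, imaged at 10 px/mm. Trajectories are per-second centroid
positions `(t, x, z)`; durations are always computed from timestamps, never
from frame counts times an assumed rate, so any uniform sampling rate works.
Missing detections carry an explicit boolean mask (and a separate mask for
frames the tracker filled by interpolation) rather than sentinel values.

## Behavioral simulator

The generator is a semi-Markov state model, not a per-frame Markov chain:
dive durations in this assay are long-tailed and strongly
species-dependent, which per-frame transition probabilities (geometric
dwells) cannot express.

* **Shallow states.** Surfacing and digging alternate with lognormal dwell
  times parameterized by their arithmetic mean (seconds) and log-space
  shape, so configured means are directly recoverable from simulated bouts.
  Within a bout, depth follows a mean-reverting (AR(1)) walk around the
  state's typical level, clipped to the state's depth band, with small
  independent frame jitter on top. Constant per-bout levels were rejected:
  they collapse the effective sample size of the pooled depth density to
  the number of bouts and create spurious local minima in the KDE.
  Horizontal position is a mean-reverting walk about the chamber
  centerline, frozen during dives (the narrow chamber forces vertical
  dives).
* **Dive excursions.** The number of dives per trial is Poisson at the
  configured rate; start times are placed by drawing sorted uniform offsets
  in the dive-free time (a "spacer" construction), which forbids overlap
  and keeps the realized cohort mean equal to the rate except when drawn
  excursions physically cannot fit in the 900 s trial. Each dive descends
  at constant speed `v` from the current digging level to a maximum depth
  drawn from a truncated normal, optionally holds that depth for a
  lognormal **bottom-search dwell**, then ascends at `v`. The target depth
  is snapped to the `v`-grid so that with the bottom dwell and positional
  noise disabled every in-dive frame increment is exactly `v` and the mean
  path speed of a dive recovers the configured speed to 1e-6. The bottom
  dwell exists because a purely triangular profile spreads dive occupancy
  uniformly in depth, leaving the pooled density monotone below the digging
  mode — with a bottom phase the density acquires the deep occupancy mode
  that makes the threshold procedure well-posed, at the cost of the speed
  metric averaging below `v` for those dives.
* **Drowning.** Time spent below the dive threshold beyond an aerobic
  limit accrues a per-second drowning hazard; a drowned larva freezes in
  place for the remainder of the trial (`drowned_at` recorded in ground
  truth). With hazard zero no trial ends immobile.
* **Escapes.** With a per-trial probability, one excursion above the
  air-chamber top of roughly 45 s is inserted, exercising the 30 s escape
  rule.
* **Ground truth.** True states are assigned from depth by the same
  partition the classifier uses, with the preset threshold; true dives are
  the maximal below-threshold runs. Cohorts derive per-trial seeds as
  `SeedSequence((root, index))`, so trial *i* is independent of cohort
  size.

### Condition presets

Presets encode the experimental groups through parameter shifts; their
calibration anchors are cohort means: 4.1 dives/trial for the baseline
melanogaster 0.4% gel, 5.3 with the attractive odor (plus deeper, longer
dives), 0.3 with blocked posterior spiracles, 1.9 for *D. suzukii* at 0.4%
with roughly tenfold longer dives and a much higher aerobic limit, 1.0 for
suzukii with blocked spiracles, and surface-dominated soft (0.05%, with
frequent drowning among the rare deep dives) and hard (2.0%) gels. A ±20%
tolerance on these anchors is the calibration contract; dive rates land
within a few percent, the duration ratio near 9. One deliberate trade-off:
the pooled mean depth of the baseline cohort sits near −1.9 mm rather than
the −2.7 mm of the original data, because mean depth is dominated by dive
occupancy, and matching it while holding the dive-count and dive-duration
anchors (which are quantitative) would require implausibly long or frequent
dives. The recovered dive thresholds (≈ −3.7 mm melanogaster, ≈ −4.0 mm
suzukii) bracket the reported −3.6 / −3.4 mm.

## Renderer and tracker

Frames are 8-bit grayscale: uniform background (level 40), chamber walls at
a distinct level (120, 2 px), the larva a filled axis-aligned ellipse
(semi-axes 1.0 × 0.45 mm, level 200), plus clipped additive Gaussian noise.
The mapping is `row = surface_row − z·px_per_mm`, `col = center_col +
x·px_per_mm`; the renderer returns the calibrated geometry alongside the
stack.

Tracking is absolute background difference → threshold (Otsu by default,
fixed override) → binary opening (radius 1 px) → connected components →
intensity-weighted centroid of the largest component with at least the
minimum area (8 px). Area ties break by larger summed difference intensity,
then smaller centroid row. The intensity weighting gives sub-pixel accuracy
(~0.1 px RMSE at noise sd 3).

Two background models are provided. The pixel-wise temporal **median** is
correct when the animal occupies each pixel less than half the time — the
property its unit test constructs. Larvae, however, commonly dig in place
for well over half a trial, and the median then retains a ghost of the
animal that distorts detections by several pixels exactly at the modal
position. `track_stack` therefore defaults to a low temporal **percentile**
(q = 10) background: because the larva is brighter than everything else in
a static chamber, the 10th percentile stays clean up to ~90% per-pixel
occupancy, at the cost of a downward bias of order the noise level that the
adaptive threshold absorbs. Detection gaps no longer than 3 s are linearly
interpolated (flagged as interpolated); longer gaps stay missing —
conservative for dive durations.

## Classifier

The pooled depth density is a Gaussian-kernel KDE with Silverman's
rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` on a 0.05 mm grid
spanning the data range ± 3 bandwidths; the density is renormalized to unit
trapezoidal integral on that grid (the truncated kernel tails otherwise
leave ~1e−3 mass outside it). The dive threshold is found by scanning the
grid downward from the sample mean for the first strict local minimum
(`d[i] < d[i−1]` and `d[i] < d[i+1]`; exact plateaus break toward the
shallower end). A monotone density raises an explicit no-minimum error —
never a silent default; the pipeline exposes a configured fallback that the
caller must opt into. Thresholds are estimated once per species from the
pooled baseline cohort and applied across that species' conditions;
surface-dominated cohorts (blocked spiracles, hard gel) do not carry a
meaningful valley of their own.

Validation of the threshold estimator compares against the minimum of the
**kernel-smoothed analytic mixture density** (each Gaussian component's
variance inflated by the bandwidth squared), which is the closed form of
what the KDE estimates; on 70/30 two-Gaussian mixtures with n = 10,000 the
recovered valley stays within 2 grid steps (0.1 mm) of it across 20 seeds.
The raw (unsmoothed) mixture minimum differs from both by a fixed smoothing
shift of ~0.2 mm that no sample size removes — comparing against it would
measure the estimator's bandwidth, not its correctness.

Classification is a pure depth partition (escape above the air top, then
surfacing/digging/diving by the two thresholds); missing frames inherit the
previous label, a missing lead-in defaults to surfacing. The escape flag
requires one **contiguous** out-of-arena run strictly longer than 30 s (the
stricter reading of the rule; run duration = frame count × sampling
interval) and excludes frames from the run start onward while still
counting the trial as escaped. The inactivity flag excludes a terminal
segment during which the animal is submerged and its rolling 120 s path
displacement stays below 0.2 mm until trial end (the tail must be at least
one window long); on the soft-gel preset this recovers the drowned/not
drowned ground truth in ≥ 95% of trials. The criterion is automated here,
whereas the original screening was visual; both parameters are exposed.

## Analytics

Dive events are maximal runs of diving labels; duration is frame count ×
sampling interval, so event durations sum exactly to total diving time.
Maximum depth is the most negative `z` in the run. Mean dive speed averages
per-frame centroid increments within the run — path speed
`√(Δx²+Δz²)/Δt` by default, vertical `|Δz|/Δt` by flag; single-frame dives
have no within-run increment and get NaN. Dives count with a single sample
below threshold; there is no minimum-duration filter.

The sliding mode probability averages the per-frame mode indicator over
non-excluded trials, then applies a centered moving average of the window
width (60 s default), truncated at the edges without padding; with a
one-sample window it equals the unsmoothed mean. Post-dive pairs join each
dive's duration to the surfacing+digging time before the next dive;
intervals censored by trial end are dropped (keeping them would bias the
correlation). Rank correlations use exact permutation p-values up to n = 8
pairs and the asymptotic approximation beyond. ECDFs are right-continuous
with final value 1.

## Statistics

* **Lilliefors normality test**: KS distance between the ECDF and a normal
  fit to the same sample; the p-value comes from a seeded Monte-Carlo null
  (Gaussian samples of the same n, parameters re-estimated per replicate),
  since table approximations are what made the plain KS test invalid here
  in the first place. The statistic agrees with statsmodels' to 1e−10.
  Note its power against Uniform(0,1) is only ~0.58 at n = 100; near-certain
  rejection of uniform data needs n ≈ 300.
* **Rank-sum (Mann-Whitney)**: exact enumeration when the pooled sample is
  ≤ 12 without ties, otherwise the tie-corrected normal approximation with
  continuity correction; a U statistic at its null mean reports p = 1.
* **Kruskal-Wallis + post hoc**: tie-corrected KW, all pairwise rank-sum
  tests Bonferroni-multiplied by the number of pairs (capped at 1), and a
  compact letter display built from the maximal cliques of the
  not-significantly-different graph, so two groups share a letter iff
  their corrected p ≥ α.
* **KS two-sample**: asymptotic two-sided p. Because the statistic is
  discrete, its attainable size at n = 50 per group fluctuates around
  0.03–0.05; null-calibration checks therefore use n = 100 per group,
  where the asymptotic approximation is valid and the type-I error sits at
  0.05 ± 0.02.
* **Effect size**: Cohen's d with the pooled sd by default (control-group
  sd by flag).
* **Power and sample size**: two-sided one-sample t via the noncentral-t
  distribution (ncp `d√n`, df `n−1`; two-sample variant provided). The
  sample-size search returns the smallest n with power ≥ 0.8 and
  reproduces the two analytic design anchors n₀ = 34 (d = 0.5) and n₀ = 6
  (d = 1.5) exactly.
* **Test selection**: both samples pass Lilliefors at α = 0.05 → pooled
  two-sample t with Cohen's d; otherwise rank-sum. The result records the
  branch taken.
* **Assay formulas**: preference index `(N_A − N_B)/N_total`, survival
  ratio `adults/larvae`, mouth-hook contraction rate `count·60/window`.

## Problem sizes and numerical choices

The test suite simulates up to 200 trials per check, uses 2000 null
replicates for test calibration, 10⁵ replicates for the power cross-check,
and 200 rendered frames for the tracker loop; the acceptance script uses
100 trials per condition. KDE grid step 0.05 mm; trapezoidal
renormalization tolerance 1e−6; dive-threshold determinism is exact for a
fixed grid. Pipeline reports are byte-reproducible for a fixed seed and
config (PNG figures excluded from that contract).

## Known limitations

The simulator does not model posture, peristalsis or odor-gradient physics
(conditions enter only through preset parameter shifts); dive counts are
Poisson, underdispersed relative to the reported cohort s.d. (means are the
calibration contract); the pooled mean depth trade-off above; and passing
closed-loop tests show the pipeline recovers what the generator encodes —
they cannot certify performance on real video, where posture change,
lighting drift and occlusion at the gel interface are the dominant failure
modes.
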