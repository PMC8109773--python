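# Methods

## The two fixation-duration metrics

Both metrics aggregate the durations of a trial's fixations toward a target
in stimulus (image-pixel) space; they differ only in the weighting kernel.

**AOI dwell time.** Given a rotated-ellipse Area of Interest with center
(cx, cy), semi-axes (a, b) and rotation θ, a fixation at (x, y) is *inside*
iff

    ((Δx·cosθ + Δy·sinθ)/a)² + ((−Δx·sinθ + Δy·cosθ)/b)² ≤ 1

with Δx = x − cx, Δy = y − cy (boundary inclusive). Dwell time is the sum of
durations of the fixations inside — equivalently, durations weighted by the
ellipse's uniform indicator kernel.

**Weighted Sum Durations (WSD).** A Point of Interest (POI) is a single
pixel location p. Each fixation f with duration d_f contributes

    WSD = Σ_f w(‖x_f − p‖) · d_f,   w(r) = round(exp(−r² / 2σ²), 3)

the peak-normalized isotropic bivariate Gaussian kernel. Weights are
normalized to [0, 1] by construction and rounded to three decimal places
*before* multiplying the duration ("the weights were rounded" refers to
weights, not products), so the kernel's working values are reproducible
exactly: with σ = 0.75° a fixation 1° from the POI receives weight 0.411 and
a fixation 2° away receives 0.029. Weights of fixations beyond
σ·√(2·ln(2·10³)) ≈ 3.9σ round to zero. Fixations outside the image bounds
still receive weight — drift correction can legitimately move gaze past the
stimulus edge, and clipping would bias the metric.

σ is stored in visual degrees and converted per display geometry (default
60 px = 1°, a 24-inch 1920×1080 monitor at 95 cm), so one kernel
configuration transfers across rigs. The default σ = 0.75° (45 px) is the
pooled average isotropic SD of fixation clusters matched to AOIs (below); a
supplementary variant uses σ = 0.85°, i.e. a full width at half maximum of
2° — the approximate diameter of foveal vision (`fwhm_to_sigma(2.0)`).

## Preprocessing

Raw fixation reports are in screen pixels. The pipeline applies, in order:

1. **Offset correction** — translate by the centered-image offset
   ((screen_w − image_w)/2, (screen_h − image_h)/2); exact, invertible.
2. **Drift correction** — the first fixation of each trial is carried over
   from clicking a required central dot, so it is taken to *be* the dot:
   all fixations shift by (dot − first fixation), the vector and its
   magnitude in degrees are recorded, and the first fixation is excluded
   from all metrics (kept in storage with its flag so the correction stays
   re-derivable and idempotent).
3. **Trial filtering** — a trial is discarded if its non-first fixation time
   is strictly below 3,000 ms (half the 6-second display; inattention or
   track loss), or if its drift magnitude exceeds mean + 3·SD pooled over
   all trials (sample SD, n − 1). Both reasons can co-occur; trials are
   flagged, not deleted. The drift criterion is computed on all
   drift-corrected trials, before the duration filter; with fewer than two
   trials it is skipped with a warning. The SD rule uses pooled trials (not
   per participant) to mirror a dataset-level outlier definition.
4. **Rating standardization** — violence ratings are z-scored within
   participant (sample SD) over retained trials; participants with fewer
   than two distinct ratings yield missing values with a warning.

## Data-driven POI definition

Per image, the corrected fixation locations of all participants are pooled
and fitted with spherical Gaussian mixtures (every component's covariance is
σ²I) by EM, delegated to scikit-learn's `GaussianMixture` with k-means
initialization; repeated fits use seeds `master_seed + repeat_index`. The
component count k is chosen by grid search (default k ∈ 1..50, 50 repeats
per k): the k with the least *average* BIC over converged repeats wins, and
the single lowest-BIC converged fit at that k is retained. BIC uses
p·ln(n) − 2·ℓ̂ with p = 4k − 1 free parameters (two mean coordinates and one
variance per component, k − 1 mixing weights) — pinned explicitly so the
criterion is reproducible independent of the backing library. Non-converged
fits are excluded from the average and logged.

Components are matched to the study's AOIs geometrically: a component is a
candidate for an AOI iff its mean lies inside the ellipse; candidates are
assigned greedily by descending mixing weight (ties by distance to the AOI
center), each component serving at most one AOI. The original procedure did
this matching by human inspection, so a manual-override table
(image, label → component index or none) is supported to reproduce hand
matching. Matched AOIs take the component mean as their POI (provenance
`gmm_component`); unmatched AOIs — no fixation cluster nearby — fall back to
the AOI center (`aoi_center_fallback`). The WSD σ is the plain arithmetic
mean of the isotropic SDs of all matched components pooled across images,
reported unrounded in px and degrees together with its SD; rounding to a
presentation value such as 0.75° is left to the analyst.

## Saliency covariates

Physical-saliency maps are *inputs* — dense nonnegative per-pixel grids from
any published saliency model (the emulated study used Graph-Based Visual
Saliency); this package does not implement one. The covariate for a target
applies the *same* kernel as the corresponding metric (ellipse indicator for
an AOI, rounded Gaussian for a POI) to each pixel's saliency, sums, and
normalizes by the total saliency of the image. Pixel centers sit at integer
coordinates. Whether the original computation rounded kernel weights here is
unstated; the default mirrors the WSD rounding and a `round_weights=False`
flag is exposed. With rounding on, pixels beyond the 3.9σ cutoff contribute
exactly zero, which licenses the windowed (cropped) evaluation.

## Trial-level mixed models

Every analysis is a linear mixed-effects model at the trial level:

    outcome ~ predictor + saliency [+ aoi_area] + (1|participant) + (1|stimulus)

Outcomes are the per-trial metric summed over the analysis's target labels
(both faces for the face analyses). The predictor is the image condition
(treatment-coded, `friendly` reference, so violent-vs-friendly is one
coefficient) or the within-participant z-scored rating. The saliency
covariate always enters, uncentered by default (a centering flag exists);
AOI area enters only for the dwell-time outcome — POIs and their kernels
share one size, so there is no size to control for.

Fitting is REML via statsmodels `MixedLM`, expressing the two crossed random
intercepts as variance components on a single all-ones group. Because
millisecond-scale outcomes produce badly conditioned likelihood surfaces,
the model is fitted on internally unit-scaled variables (REML estimates are
equivariant under linear rescaling; coefficients and CIs are mapped back)
with an optimizer cascade (lbfgs, then Powell, then Powell-refined-by-lbfgs)
that accepts the first converged solution. Wald t and p values use the
normal approximation; a cross-check backend through R's lmerTest
(Satterthwaite degrees of freedom, the reference behavior) is provided and
exercised in the test suite — at trial-level sample sizes the two agree
closely. Marginal and conditional R² follow the usual variance partition
(fixed / total and fixed+random / total). Convergence failure is reported
through a flag, never raised; rank-deficient fixed-effect designs raise with
the offending column named.

## Noise-robustness experiment

White Gaussian position noise (iid per coordinate, justified by
artificial-eye recordings of video trackers) is added to the drift-corrected
fixation locations — by default one draw per trial, i.e. a rigid
translation; per-fixation and per-participant units are available. Per
repetition the two metrics are recomputed with the *original* AOI/POI
definitions (filters are not re-run), the rating → face-metric model (the
weakest relationship in the emulated study) is refitted once per outcome on
the same perturbed data, and significance is tallied at α ∈ {0.01, 0.05,
0.1} over converged fits only, with denominators reported. Repetition seeds
are `master_seed + rep`; the same rep seed is reused across noise levels
(common random numbers). The reference experiment used 1,000 repetitions at
SDs of 0.25–1°; the desk-scale configuration in the test suite uses 20
participants × 24 images, 200 repetitions and SDs {0.5°, 1°}, which is
sufficient to resolve the qualitative ordering of the two metrics.

## The synthetic-data generator

The generator emulates the structure of the emulated study: 90 participants
× 72 images (1600×900 px centered on 1920×1080), 6 s of viewing per trial,
violent/friendly/ambiguous conditions in equal thirds, contact points on 37
of 72 images, and a 1–7 violence rating per trial. Key modeling choices:

- **Attention mixture.** Fixation locations are drawn iid from a mixture of
  isotropic Gaussians (σ = 0.75°) at the latent targets (two faces and,
  where present, a contact point) plus a broad background component (6°) at
  the image center. Baseline weights: 0.28 per face, 0.16 contact,
  remainder background.
- **Rating/gaze coupling.** A latent per-trial perceived violence
  (condition mean 5.5/3.5/2.0 + N(0,1)) produces both the integer rating
  (rounded, clipped to 1–7) and multiplicative attention modifiers:
  per centered violence unit, face weights shrink by 6% and contact weight
  grows by 12%. Coupling gaze and rating through one latent variable is what
  makes the *trial-level* rating effect recoverable — a stimulus random
  intercept absorbs purely image-level differences.
- **Participant heterogeneity.** Each participant carries a face-preference
  factor (SD 10%), giving the participant random intercept genuine variance.
- **Durations.** Lognormal, median 250 ms, log-SD 0.55 (fixation durations
  are right-skewed); fixations are emitted until the 6,000 ms budget is
  exhausted (the last one truncated), so the count per trial is emergent,
  not fixed. 2% of trials are "inattentive" (800–2,800 ms of recording) so
  the duration filter has realistic work; with the drift-outlier rule this
  yields a ~2–4% discard rate, the scale of the emulated study's 4.5%.
- **Drift.** Each trial's fixations are displaced by a drift vector with
  iid normal components scaled so the mean magnitude is 1.32°; the study's
  reported drift SD (1.39°, right-skewed) is *not* reproduced — a known
  simplification. The first fixation sits exactly on the central dot plus
  drift, so drift correction recovers true image coordinates exactly.
- **AOIs.** Ellipses centered on the true targets with semi-axes defined in
  degrees (defaults ≈ 65×80 px faces, 45 px contact at 60 px/°), jittered
  ±18% in size and ±0.3 rad in tilt per image, as hand-drawn AOIs vary.
  The sizes are calibrated so the boundary sees realistic traffic: with
  0.75° clusters they reproduce the emulated study's zero-dwell statistics
  (~30% of contact trials, very few face trials). This matters: with
  oversized AOIs the dichotomous boundary almost never acts and dwell time
  would look spuriously noise-robust.
- **Saliency.** Toy maps (Gaussian bumps at the targets over a constant
  floor) stand in for real saliency-model output; they are labeled synthetic
  and generated lazily at full image resolution.

What the generator does **not** emulate: saccade dynamics and scan-path
order (fixations are iid draws), spatial anisotropy of fixation clusters,
heavy-tailed drift, tracker-specific structured noise (pink noise,
calibration decay), and real image content. Passing tests therefore
demonstrate that the *pipeline* recovers planted structure under the stated
statistical model, not that the metrics behave identically on any real
dataset.

## Desk-scale problem sizes

The test suite validates the full pipeline at the study scale (90 × 72) for
effect-sign recovery, and uses reduced designs elsewhere as the package's
own desk-scale choices: the robustness experiment runs 20 × 24 with 200
repetitions at two noise levels; null calibration runs 400 independent
20 × 24 studies with zero planted effects (observed type-I rate ≈ 0.04–0.05
at α = 0.05); GMM recovery runs 20 seeded searches over k ∈ 1..10 with 10
repeats on n = 1,000. The study-scale runs use the AOI-center POI variant
(the emulated study's own supplementary analysis) so the grid search over
k ∈ 1..50 × 50 repeats × 72 images is not on the critical path; GMM-based
POI definition is validated separately at per-image scale.

## Numerical notes and degenerate inputs

- Weight rounding uses IEEE round-half-even (`np.round`); no worked value
  sits on a .0005 boundary, so this is inconsequential in practice.
- `reg_covar = 1e-6` floors component variances in EM; a component at the
  floor is flagged (`sigma_floored`) rather than silently accepted.
- BIC ties across k resolve to the smaller k.
- Empty trials cannot be drift-corrected (error); single-fixation trials
  yield zero analyzable fixations and a 0 for every metric.
- Zero-variance outcomes and optimizer failures mark the fit non-converged
  instead of raising, so batch experiments never abort mid-run.
- A zero-total saliency map is an error (normalization undefined).
- CSV readers parse floats in round-trip mode; definition files survive
  write→read bit-exactly.

## Known limitations

- Normal-approximation p-values are mildly anti-conservative in very small
  designs (few stimuli with an image-level predictor); the lmerTest backend
  exists for exact Satterthwaite inference where that matters.
- The component→AOI matcher is purely geometric (mean inside ellipse);
  semantically meaningful clusters that straddle an AOI boundary need the
  manual-override table.
- Only elliptical AOIs and Gaussian POI kernels are implemented — by design;
  rectangular/freeform AOIs, scan-path metrics and saliency-model
  implementations are out of scope.
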