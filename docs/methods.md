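# Methods

## The encoding model

Every cortical vertex is modeled as an isotropic 2D Gaussian receptive
field in visual space, G(u, v) = exp(−((u−x)² + (v−y)²) / 2σ²), with center
(x, y) and size σ in degrees of visual angle (DVA). The neural drive to a
binary (or, after TR resampling, fractional) aperture frame s(t) is the
stimulus–Gaussian overlap raised to a compressive exponent n (compressive
spatial summation), scaled by a gain g:

    r(t) = g · (Σ_pixels s(t) ⊙ G)^n,

then convolved with a fixed double-gamma hemodynamic response function
(response peak 6 s, undershoot peak 16 s, unit dispersions, undershoot
ratio 1/6, 32 s support, normalized to unit sum and sampled at the TR).
With n = 1 the model is exactly the linear overlap model; n < 1 compresses
spatial summation, which is the regime observed beyond V1. The model grid
is 101×101 pixels spanning ±radius; x is positive rightward, y positive
upward, and grid row 0 is the top of the visual field — this convention is
realized in exactly one function (`FieldGeometry.coords`) and in
`ScreenGeometry.pixel_to_degrees` on the eye-tracking side.

Derived quantities: eccentricity √(x²+y²); polar angle atan2(y, x) in
degrees, defined as 0 at the origin; variance explained R² = 1 −
SS_res/SS_tot with SS_tot about the observed mean. "Size" always means the
raw σ; the CSS effective size σ/√n is exposed as a derived field
(`PRFParams.effective_sigma`) but never enters summaries.

## The stimulus

A bar of width 2° sweeps across a disc of radius 11.5° along four axes
(vertical, horizontal, and the two diagonals fixed at 45°/135°), two
directions per axis — eight sweep configurations. The bar center advances
linearly from −radius to +radius over 30 s (continuous motion, sampled at
4 Hz); a 12 s mean-luminance blank follows every second sweep. Apertures
are binary by pixel-center inclusion and clipped to the disc; averaging
happens only at the TR-resampling stage, where each 2 s bin is the mean of
its source frames, preserving total stimulus energy to within one frame.
The sweep order (axes in declared order, forward direction first) and blank
placement are fixed and recorded in the aperture sidecar; reversing a
direction yields exactly the time-reversed mask sequence of its partner.

## Fitting

Observed and predicted series are mean-removed before comparison (the
percent-signal-change convention), which makes fits invariant to additive
offsets. Stage 1 evaluates a coarse grid — 15×15 centers over ±1.5 radius,
8 log-spaced σ from 0.5° to 2 radius, exponent fixed at 0.5 — solving the
non-negative gain per candidate in closed form; ties in RMSE resolve to the
smaller σ, then scan order. Stage 2 refines (x, y, σ, n) with bounded
Powell search (|x|,|y| ≤ 2 radius, σ ∈ [0.1, 3 radius], n ∈ (0.05, 1],
iteration-capped), the gain still analytic. Both stages are deterministic:
identical inputs give bit-identical fits.

For cohort-scale simulations (tens of thousands of vertices)
`fit_prf_batch` evaluates a denser shared grid (23×23 centers over ±1.1
radius, 8 σ) with analytic gains and no per-voxel refinement; candidate
predictions are computed once per (movie, HRF, grid) and cached. Two
numerical choices matter here. First, centers are kept within ~the
stimulated region: candidates far outside the aperture produce nearly flat,
mutually degenerate predictions whose ties noise breaks toward the
extremes, inflating eccentricity for large-σ voxels. Second, grid-only
fits quantize parameters at the grid spacing (~1.1° for centers); ROI-level
means average this out. Even so, eccentricity estimates carry a positive
bias (~+0.5° foveally, ~+1.2° beyond 6°) because pRFs extending past the
11.5° aperture are weakly constrained — a property of the measurement, not
of the optimizer, and one reason ROI mean eccentricities run slightly above
their generative truth. Under noise, σ and n also trade off (larger σ with
larger n can mimic the same prediction), so single-vertex σ estimates are
noisy where center estimates are not; comparisons therefore always operate
on ROI means over many vertices.

The R² > 0.1 inclusion filter is calibrated against pure-noise series:
with the default protocol (144 TRs), noise-only voxels pass in well under
10% of cases (~0–2% observed over 200 replicates).

## Gaze statistics

Screen geometry follows the viewing setup: a 597 mm-wide monitor at 570 mm
subtends 2·atan(w/2d) ≈ 55.3° horizontally and, with square pixels at
16:9, ≈ 32.8° vertically. Frames are extracted at 0.2 Hz at bin midpoints
(six per 30 s clip; a clip shorter than one period contributes its
midpoint frame), and the gaze sample nearest each frame time is used (the
log's sampling rate is immaterial to this rule). The fixated category is
the label of the pixel under gaze; face labels take precedence where face
and body overlap; invalid or out-of-bounds samples are flagged and excluded
from denominators.

For the retinal image, each frame is translated so the gaze pixel sits at
the canvas center and cropped to monitor dimensions. Padding introduced by
the shift contributes to *no* category: the per-pixel category probability
is unconditional (count of frames showing the category divided by the
number of frames), so the three images sum to ≤ 1 pixelwise. This differs
from dividing by per-pixel coverage, which yields conditional probabilities
that peak far off-center by construction (rarely covered canvas regions are
covered mostly during low fixations, where faces sit ~+11.6° up), and
from counting padding as scene, which inflates the scene category at the
edges; the scene-padding convention is available as `padding="scene"`.
Marginal profiles average the probability image along the orthogonal axis,
normalize to their maximum, and report the peak in DVA with ties broken
toward the center. Peak comparisons are paired two-tailed t tests on one
peak coordinate per participant.

## Synthetic data: what it emulates, and what it does not

`gen_sheet` builds a cortical sheet per participant: a medial-to-lateral
axis a ∈ [0, 1] split into seven equal anatomical ROIs (CoS, FG-medial,
FG-lateral, OTS, ITG, ITS, MTG; positions coded 1..7). Ground-truth
eccentricity follows ecc(a) = e_min + amp·(a − a₀)² with e_min = 3°,
amp = 10, trough a₀ = 0.4 (the FG-lateral/OTS boundary, position ≈ 3.3),
plus vertex jitter (SD 1°) and a participant offset (SD 0.5°); linear and
flat truths are available as effect dials so gradient verdicts are testable
in all three regimes. σ grows linearly with eccentricity (1.5 + 0.8·ecc);
gain is 1 and the exponent 0.5 throughout. Category clusters (CoS-place,
pFus-face, OTS-limb) occupy sub-intervals of their anatomical ROIs; their
members' eccentricities are drawn around the reported group values (place
6.5°, face 3.6°, limb 5.8°) and their pRF centers fall in the lower visual
field with elevated probability (limb 0.75, face 0.62, place 0.57, baseline
0.55). Because those absolute eccentricity values are themselves part of
the U-shaped study conditions, they apply only under the U truth; under the
flat/linear dials clusters inherit the local truth so that the null really
is null. The default cohort is 27 participants × 7 ROIs × 200 vertices.

`gen_bold` produces BOLD as forward-model prediction plus white Gaussian
noise whose SD is a fraction of the cohort's reference amplitude (median
peak-to-trough of clean predictions); the default 0.5 yields fitted R²
around 0.3, the level reported for ventral category-selective cortex.
`gen_localizer` produces a ~209 s six-condition block design (4 s blocks,
shuffled, occasional baseline) in which cluster vertices respond 1.0 to
their preferred category and 0.3 otherwise, non-selective vertices respond
0.3 to everything, with noise SD 0.3 — chosen so truly selective vertices
clear the t > 3 labeling threshold reliably, as real functional ROIs do.

`gen_movie_dataset` renders each extracted frame as a face rectangle
(176×144 px at 640×360, 11% of pixels) above a stacked body silhouette
(shoulders, a tapered torso widest exactly at the configured offset below
the face center — default −11.6° — and legs; ~32% of pixels net). The
taper is an identifiability choice: a rectangular body yields a flat-topped
marginal profile whose argmax is set by the tie-break rule rather than by
the configured offset. Fixations land on the face with probability 0.66,
the visible body with 0.174, else background, with within-target scatter of
SD 30 px (~2.6°, comparable to the face half-extent — humans scan features
within a face; a point-like policy leaves the face marginal flat-topped and
its zero offset unidentifiable). Logs are written at 10 Hz with small
tremor and occasional invalid samples; the analysis is invariant to log
rate. Frames are generated at 640×360 with the physical screen geometry, so
angular quantities are unchanged and only pixel quantization differs from
the 2560×1440 instrument.

What the generators do **not** emulate: real image content and saliency,
smooth pursuit and saccade dynamics, temporally autocorrelated or
physiological fMRI noise (an AR-free white-noise default; the fitter does
not depend on noise color), cortical surface geometry and inter-subject
alignment, hemodynamic variability across vertices, and horizontal
asymmetries of body positions (the synthetic body-peak x coordinate is ~0
by construction, unlike real film statistics). Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under known
ground truth, not properties of real recordings.

## Group statistics

All group comparisons are random-effects: exactly one summary value per
participant per ROI enters any test, and p values are always two-tailed.
ROI summaries average unweighted over vertices with R² > 0.1 (strict);
participants lacking a surviving vertex in either ROI of a pair are
excluded from that comparison. The within-subject ANOVA uses the standard
one-way repeated-measures decomposition with df = (k−1, (k−1)(n−1)) and no
sphericity correction; identical columns return F = 0, p = 1, and
incomplete participants are listwise-deleted with a logged count. The
gradient model comparison is descriptive, as in the original analysis:
pooled OLS of participant-ROI cells on position 1..7 (a group-means mode
exists), reporting R² and RMSE for the linear and quadratic fits; an
optional nested F test is provided but does not drive the verdict. A
"reversal" verdict requires an upward quadratic (c > 0), a trough strictly
inside (1, 7), and a quadratic R² advantage above a margin (default 0.02);
an upward quadratic with an out-of-range trough is classified monotone, and
a sub-margin advantage is inconclusive. Hemispheres are tagged and analyzed
separately; the synthetic default generates one hemisphere.

## Problem sizes and determinism

Default study-scale runs use 27 participants × 200 vertices/ROI with
batch (grid) fitting; recovery and null benchmarks use the full two-stage
fitter on 50–200 single vertices; the multi-seed gradient-replication
suites run 27-participant cohorts at 25 vertices/ROI, and ANOVA power
checks run at the matrix level (ROI means drawn directly around their
truths), which is the appropriate scale for those questions. Every source
of randomness flows from an explicit seed; reruns with identical
configuration produce byte-identical output tables. In the acceptance
benchmark, "noise SD equal to the signal amplitude" is implemented as noise
SD equal to the RMS (standard deviation) of the clean prediction — the
SNR = 1 convention; under the peak-to-trough reading, voxels whose pRFs
barely overlap the aperture are unrecoverable for any fitter.

## Known limitations

- Eccentricity is overestimated for pRFs near and beyond the stimulus
  border (see Fitting); gradient conclusions rest on the shape across ROIs,
  which is preserved.
- σ and the CSS exponent are partially degenerate under noise; reported σ
  comparisons are ROI-level.
- The batch fitter quantizes at its grid resolution and does not refine
  per voxel; use `fit_prf` (or `fit_prf_batch(..., refine=True)`) where
  single-vertex precision matters.
- The pixels-per-degree conversion is linear (small-angle) across the
  screen; at ±27° the true local magnification differs by a few percent.
- FreeSurfer-style label files are read as plain vertex lists; no surface
  geometry is handled.
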