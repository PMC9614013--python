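# Methods

This note documents the models and procedures implemented in
`infantmotion`, the parameters that matter, the design choices made
where the design was genuinely open, what the synthetic data do and do
not emulate, and the package's known limitations.

## Image pipeline

**Brightness and foreground.** Colour frames are converted to
brightness with the Rec. 601 luma weights (0.299 R + 0.587 G +
0.114 B). The silhouette is `|frame − background| ≥ T` with `T = 80`
grey levels (config `threshold_T`). The absolute difference makes the
segmentation symmetric for bright-on-dark and dark-on-bright scenes;
with the intended scene (white-wrapped infant on a black mat) the two
conventions coincide.

**Interframe difference and denoising.** Silhouette stacks are
differenced frame by frame (XOR of binary masks; the first frame of
every sub-segment is all-zero, since it has no predecessor inside the
sub-segment). Salt-and-pepper artifacts are removed by `morph_iterations
= 3` erosions followed by 3 dilations with a 3×3 square element — an
opening by the iterated element, hence idempotent and never
pixel-adding. Structures thinner than about 7 px do not survive this
opening; consequently only movements displacing an edge by more than
roughly 7 px/frame (≈ 210 px/s at 30 fps) register in the movement
signal. This is an intentional property of the published processing
chain, not an artifact of this implementation, and it sets a resolution
floor that the synthetic scenes must respect (below).

**Sub-segments.** Frames annotated as sleep/cry/caregiver interaction
(a JSON list of half-open, 0-based frame intervals) are deleted; the
remaining maximal runs are the analysis sub-segments. Annotation is
manual by design; automatic behaviour detection is out of scope.

**Regions.** Each frame's trunk is summarised by the moment-equivalent
ellipse of the largest connected foreground component (centroid from
first moments; axes and orientation from the second-central-moment
eigendecomposition; a circular body reports orientation along the image
rows by convention). The analysis rectangle is aligned to the ellipse
axes with half-widths `(1 + rect_margin) ×` the semi-axes and is split
by its midlines into quadrants; "upper" is the half toward the
configured `head_side` (the crib fixes the head direction per
recording; it cannot be inferred from a silhouette). `rect_margin`
defaults to 1.2. A small margin cannot work: the shell between a
trunk-fit ellipse and a 1.2× rectangle is only a few pixels wide along
the minor axis, while an infant's limbs extend roughly a trunk-length
beyond the torso; the rectangle is meant to contain the whole body. With
margin 1.2 the rectangle is 2.2× the trunk ellipse per side, which
contains extended limbs at the rendered geometry and leaves the quadrant
midlines anchored to the trunk centroid.

## Per-frame quantities

With region pixel counts `P` and difference counts normalised by
`P_avg`:

- `P_avg` is the mean over e = 1..E of the running maxima
  `max(P_1..P_e)` of whole-body posture, computed within the first `Le`
  frames of the first sub-segment. Defaults `E = Le = 300` frames
  (10 s at 30 fps); both are config keys, since the source system's
  exact values are not published. For a stably visible body the running
  maximum saturates quickly, so `P_avg` is insensitive to `E` in
  practice.
- `M = (diff count in region)/P_avg`; a frame is a movement frame when
  smoothed `M` strictly exceeds `movement_threshold` (`M_th`). The
  threshold is not published; the default 0.01 (1% of reference body
  area changing per frame) keeps rendered still scenes with pixel noise
  below 1% flagged frames while real movement at the scale the opening
  passes produces `M` an order of magnitude above it.
- The iCOG is the silhouette centroid within the whole-body region;
  velocity is the scaled first difference (zero at each sub-segment
  start) and fluctuation is the deviation from `G_avg`, the mean iCOG
  over the first `Le` frames. The `1/√P_avg` scaling makes both
  dimensionless and comparable across body sizes.
- Smoothing is a second-order Butterworth low-pass applied zero-phase
  (forward–backward), cutoffs 10 Hz for `M` and 5 Hz for velocity.
  Zero-phase filtering is chosen so the spectral features see no phase
  distortion; the effective magnitude response is the squared single-pass
  response, and tests validate it against the bilinear closed form
  `|H|² = 1/(1 + (tan(πf/f_s)/tan(πf_c/f_s))⁴)`. The fluctuation series
  is left unfiltered.

## Features

26 features per infant: I1–I3 (movement fraction, mean smoothed `M`
over movement frames, movement episodes per minute) for upper and lower
body; I4–I5 upper/lower ratios of I1 and I2; I6 the zero-lag Pearson
correlation of the smoothed upper and lower movement signals (a
co-occurrence variant is available behind `coordination_mode`); I7–I12
spectral central frequency and second moment for the movement signals
(A5, A6), the velocity (x, y) and the fluctuation (x, y); I13–I14
per-axis SDs of velocity and fluctuation; I15 the convex-hull area of
the fluctuation excursion.

Spectra are Welch estimates (Hann window, `welch_nperseg = 512` at 30
fps ≈ 0.059 Hz resolution, 50% overlap, mean-detrended) integrated over
0.1–10 Hz. The band excludes DC (central frequency of a constant would
be meaningless) and is capped at the movement-signal filter cutoff.
Sub-segments are combined by duration-weighted averaging: of
per-segment spectra for the rhythm features, and by pooling frames for
the counting statistics, so that a recording of identical sub-segments
reproduces the single-segment features exactly.

Degenerate inputs: a ratio with a zero denominator returns 1 when the
numerator is also zero (identical statistics) and otherwise is capped at
`ratio_ceiling` (1e3) with a warning, preserving order directionality
without overflow; an all-zero signal yields NaN spectral features with a
"no power in band" note; a collinear fluctuation trajectory yields hull
area 0 with a warning.

Quality control discards recordings with analysable duration ≤ 180 s or
whole-body movement fraction ≤ 10% (both bounds inclusive). Short
recordings are discarded before feature extraction, since the reference
windows require a minimum length.

## Statistics

**Brunner–Munzel.** The rank-based statistic for the relative effect
`p = P(X<Y) + ½P(X=Y)` with midrank tie handling, studentised with
Satterthwaite-type degrees of freedom (`method="t"`), matching scipy's
implementation to machine precision. At the cohort's group sizes (7 vs
34) this approximation is measurably liberal: its simulated null
rejection rate at α = 0.05 is ≈ 0.066. A permutation variant
(`method="permutation"`, seeded label permutations of the same
statistic) holds the level (≈ 0.05) and is used wherever calibrated
error rates matter; the t form remains the selection default because it
is the standard reported form. Complete separation with zero rank
variance returns W = ±∞, p = 0; two entirely tied samples return W = 0,
p = 1 with a warning.

**Selection and lumping.** Features with two-group p < 0.10 (config
`retention_alpha`; deliberately lenient, no multiple-testing correction
— reproduced as stated, and documented as such) are retained. Retained
features are z-scored; connected components of the |r| ≥ 0.7 graph are
replaced by the mean of their z-scored members (raw averaging across
different units would be meaningless); singletons pass through z-scored.
Constant features are excluded with a warning before correlation.

**Exact tests.** Fisher's exact test for r×c tables uses the
Freeman–Halton rule — sum the probabilities of all margin-fixed tables
no more probable than the observed one — by full enumeration (guarded
to ≤ 4×4 tables with total ≤ 200), with a seeded Patefield Monte-Carlo
fallback. Yule's Q is `(ad − bc)/(ad + bc)` and is undefined (error)
when `ad + bc = 0`.

## Classifiers

LDA and logistic regression (unpenalised) wrap scikit-learn. The MLP is
a one-hidden-layer ReLU network with a logistic output, trained by
full-batch Adam on cross-entropy (inputs standardised on the training
fold); it is implemented directly on numpy tensors so that all folds of
a leave-one-out run train simultaneously as one batched computation —
nested tuning otherwise needs thousands of sequential fits per cohort.
The LLGMN expands the input to quadratic monomials `(1, x_i, x_i x_j)`,
allocates one softmax unit per class/component pair (the last unit's
weights pinned at zero for identifiability), and sums unit probabilities
within a class; because a Gaussian-mixture log-discriminant is quadratic,
this family contains every GMM Bayes posterior exactly (verified against
the closed form in tests), and maximum-likelihood training searches it
directly.

Leave-one-out evaluation predicts each infant from a model trained on
the rest; metrics are pooled over folds (ROC-AUC by trapezoid over
score thresholds, PR-AUC by precision steps, decision threshold 0.5, no
class reweighting despite the 7-vs-34 imbalance — as in the study
design). Nested tuning runs an inner leave-one-out on each outer
training set, scores each grid value by pooled inner F1, and breaks ties
toward smaller capacity; the whole procedure repeats
`tuning_repetitions` (default 10) times with distinct seeds and reports
the repetition with the best outer F1 (then PR-AUC) plus the mean ± SD
of tuned values. Default grids: MLP hidden nodes 2–20, LLGMN components
1–5. Per-fold random initialisations are seeded by held-out sample
identity, not position, making fold results order-invariant. Feature
selection is performed once on the full cohort before the outer loop,
replicating the study's stated order — a known optimistic bias
(selection sees the held-out label); the library API allows running
selection inside each fold instead, but the default reproduces the
published procedure.

## Synthetic data

**What it emulates.** A bright trunk ellipse (soft ~1 px edge, mimicking
camera blur) on a dark background; four limb discs orbiting attachment
points beyond the trunk's head/foot ends; per-axis sinusoidal
body-center drift plus optional random walk; Gaussian pixel noise and
salt-and-pepper specks; burst-gated limb motion; and cohort-level
feature/M-CHAT generation with group differences in the direction the
screening targets (weaker lower-limb movement, higher upper/lower
ratio, faster lateral body-center rhythm, smaller lateral excursion in
the high-risk group), scaled so a 34-vs-7 cohort is separable at
roughly leave-one-out ROC-AUC 0.9 rather than trivially.

**Why limbs orbit.** The movement signal counts changed pixels, which
track the limb's instantaneous *speed*. A linear back-and-forth
oscillation at f has speed |cos(2πft)|, whose spectrum lives at 2f and
harmonics — the planted frequency would be invisible. Each limb
therefore circles its attachment with angular speed modulated at f
(`θ(τ) = 2πfτ + β sin(2πfτ)`, β = `speed_mod`, default 0.35), making the
changed-pixel count itself rhythmic at f, with a closed path so bursts
cause no net displacement. Two geometric constraints follow from the
morphological opening's ~7 px/frame floor: orbit speeds must stay above
it (orbit radius × 2πf/f_s ≳ 10 px with moderate β), and orbits must
clear the trunk and each other — a limb sweeping over the trunk changes
no silhouette pixels while overlapped, gating the movement signal once
per revolution and biasing the recovered central frequency upward by
several tenths of a Hz (observed before the design was fixed).

**Label consistency.** Cohort M-CHAT items are Bernoulli draws per
group, resampled (bounded retries) until the questionnaire cutoff
reproduces the intended group label, so labels always equal the scored
risk.

**What it does not emulate.** Articulated kinematics, occlusion,
illumination changes, camera shake, head/face regions,
realistic correlation structure among the 26 features (cohort features
are independent Gaussians within group), or any coupling between the
questionnaire items and the movement features beyond the shared group
label. Passing recovery tests therefore demonstrates that the pipeline
measures what it claims on scenes satisfying its assumptions — not that
the features discriminate real clinical groups.

## Problem sizes in the validation suites

Rendered validation scenes are 480×360 (limbs) and 320×240 (drift),
48 s at 30 fps — large enough that limb speeds clear the morphology
floor with study-default parameters, small enough to analyse in about a
minute. The calibration suites use 10,000 null simulations for the
type-I error, 1,000 cohort seeds for selection power, and 100 seeds
(nested tuning with grid {4, 8, 12} hidden nodes, one repetition, 100
Adam epochs) for the end-to-end screening recovery; these sizes give
Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

- The trunk fit assumes one dominant connected component; a limb
  touching the frame border as a separate large blob could capture the
  fit. Real recordings with severe occlusion need manual exclusion.
- `P_avg`'s construction ("mean of running maxima") follows the most
  direct reading of its definition; the source system's exact windowing
  may differ, which would rescale `M`, `G^v`, `G^d` by a near-constant
  factor and leave rank-based selection nearly unchanged.
- Movement below the morphological-opening floor (~210 px/s edge speed
  at 30 fps, 720×480) is invisible by construction; fine tremor is out
  of reach of this processing chain.
- The permutation Brunner–Munzel is Monte-Carlo (seeded); exact
  enumeration of all label assignments is not implemented.
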