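# Methods

This note documents the models and procedures implemented in
`fallert`, the defaults chosen where the design was open, and what the
synthetic test bed does and does not demonstrate.

## Background model and selective learning

Each pixel is modelled by up to 5 Gaussian components (mean per
channel, scalar variance, weight). A pixel matches a component within
3σ (Mahalanobis, `bg.match_sigma`); it is *background* when the
matching component's weight exceeds `bg.bg_weight_threshold` (0.3).
Unmatched pixels replace the weakest component. Shadows are pixels
whose brightness is 40–95% of the expected background
(`bg.shadow_lo/hi`) with consistent chromaticity on colour input; they
are excluded from foreground entirely, before contour extraction.

The model is updated through a two-pass protocol. The analysis pass
(`subtract`) classifies pixels with a frozen model. The learning pass
(`selective_learn`) runs the ordinary mixture update on a composite
frame in which all pixels under the protect mask — the union of active
subjects' bounding boxes dilated by 5 px, plus any active occlusion
zone — are replaced by the *expected background*, defined as the
highest-weight component mean per pixel. Protected regions therefore
re-learn their own background and a stationary subject never decays.

The learning rate defaults to α = 0.05 per frame. The selective scheme
is precisely what makes a rate this fast safe, and the fast rate is
what makes it useful: a displaced chair's new component reaches the
background weight threshold in ⌈log(1−0.3)/log(1−0.05)⌉ ≈ 7 frames
(about a second at 8 Hz), and slow illumination ramps track without
ghosting. A much slower rate (e.g. 0.01) would leave nuisance objects
in the foreground for tens of seconds and defeat the purpose of the
two-pass design.

Foreground contours are 8-connected components of non-shadow foreground
pixels with area ≥ 0.5% of the frame (`bg.min_area_frac`). When the
silhouette is split by similarly coloured scenery, all contours
intersecting the Kalman-predicted box expanded by 20% per side are
pooled: union bounding box, summed area, and a second-moment ellipse
fitted to the pooled pixels.

## Kalman filter

State `[x, y, ẋ, ẏ, h, w, v_r, v̇_r, φ, φ̇]` with the linear transition
x ← x + ẋ·dT (same for y, v_r, φ), rates and h, w held constant;
dT = 1/frame-rate (default 1/8 s). Measurements are (x, y, h, w, v_r,
φ). The ratio-change speed v_r is a *derived* measurement: the feature
extractor computes |r_t − r_{t−1}|/r_{t−1} from the raw box ratio and
feeds it to the filter; the classifier consumes the filtered values.
The angle innovation is folded to (−90°, 90°] so the 0°/180° wrap
never produces a spurious jump.

Noise defaults (all configurable): process std per step — position
2 px, velocity 1 px/s, h/w 1.5 px, v_r 0.05/s, angle 2°; measurement
std — position 1 px, h/w 2 px, v_r 0.1/s, angle 5°. Centroid
measurement noise is small relative to subject size, so association
gates can be tight. The published state model lists h and w (not the
ratio) in the state vector even though the ratio is what the
classifier uses; this implementation follows the state equations and
derives the ratio as w/h.

Association solves a global minimum-total-distance assignment
(Hungarian) between predicted centres and observed centroids, gated at
0.75·max(predicted w, h). Unmatched observations become *candidates*;
a candidate moving ≥ 0.5 px/frame (point-cloud evidence) for 3
consecutive frames is promoted to a track, one motionless for 5 frames
is marked uninteresting and released to background learning. Tracks
die after 10 consecutive unobserved frames unless occluded.

## Optical flow

Corners (Shi–Tomasi response peaks) are seeded inside the subject mask,
at most 100 per cloud, and advected with an iterative pyramidal
Lucas–Kanade solver (3 levels, 15×15 window, ≤ 10 iterations,
bilinear sampling; points with an ill-conditioned structure tensor or
out-of-bounds correspondence are dropped, never invented). The solver
is vectorised over points and implemented in-package on top of
numpy/scipy.

Pruning follows a two-stage statistical rule applied per frame:

1. *Base set*: the ⌊0.4·n⌋ points whose displacement magnitude is
   closest to the cloud mean (ties broken by point index).
2. *Flagging*: points whose magnitude deviates from the base-set mean
   by more than 1.5 base-set standard deviations increment a doubtful
   age (capped at 3); conforming points reset to 0.
3. *Removal*: a point at doubtful age 3 is removed when its
   displacement direction deviates more than 60°
   (`flow.coherence_angle_deg`) from the base-set mean direction — a
   magnitude deviant that still moves with the cloud (e.g. a point on
   a swinging arm) survives with its age capped. If the base set
   itself is motionless, ripe points are removed outright.

A safety bound caps removals at ⌈0.25·n⌉ per pass (worst deviators
first); clouds under 5 points are never pruned. Whether the base
metric uses magnitudes or 2-D vectors was an open choice; magnitudes
are used for flagging and direction only for removal. A cloud is
*static* when its windowed (5-frame) mean displacement is below
0.5 px/frame — deliberately below the ~1 px/frame micro-jitter of a
person standing still. Clouds reseed when they shrink below 40% of
their initial size.

## Classifier

Five features per frame: ellipse angle (folded to [0°, 90°] so left
and right falls coincide; `clf.fold_angle`), box ratio w/h, and the
three most recent filtered ratio-speed values (zero-padded at track
birth). Min–max normalisation bounds come from the training set
(clamped outside; a degenerate dimension maps to 0.5); each
ratio-speed copy is weighted 1/√3 so the triple contributes one unit
of squared Euclidean distance. k = 3 neighbours vote with weight
1/(d + 10⁻⁶); exact ties break toward FALL because a missed fall is
the costly error. Sitting is handled by training coverage plus the
alert delay, not by a third class; brief fall-like classifications in
sitting postures are expected and are absorbed by the debounce.

Training sets are built from exported track histories (CSV) plus
manually labelled frame intervals — one labelled sample per tracked
frame inside an interval — and persisted as a CSV with a JSON sidecar
holding bounds, weights and k. When training on the synthetic scenes,
interval boundaries are trimmed by 3 frames so the transition phases
(mid-deformation, neither state stable) contribute no samples;
occluded falls are excluded because their detection is rule-based.

## Occlusions

Only inferior occlusions (lower body hidden by furniture) are
modelled. Onset: over the last 4 frames, the foreground area inside
the bottom 40% of a reference box (median box over the 5 preceding
frames) dropped by > 50%, while the top edge and the upper-half width
each varied < 15% of the reference extent — a crouch fails the
top-edge condition. At onset the reference height is stored and
classification is suspended. While occluded, if no contour intersects
the occlusion zone for 8 consecutive frames (1 s), the track becomes
an occluded fall, which the alerter treats as a fall state. The
occlusion ends when the observed height returns within 20% of the
stored height. These thresholds (`occl.*`) are the least
externally-anchored part of the system: the geometric rules are stated
only qualitatively in the literature, and the values here were fixed
once against the scripted desk scenes.

## Alerting

A fall alert fires after 2.0 s (`alert.delay_s`) of uninterrupted fall
state; any interruption — including an unknown state while occluded —
resets the timer. Recovery is debounced symmetrically at 2 s, a choice
made here to avoid alert flapping when a fallen person repeatedly
half-rises; the delay for the fall direction is the externally
specified value, the symmetric recovery is this package's design.
Events per track strictly alternate alert/recovery. Delivery goes
through sinks (file sink writing message text + snapshot PNG with the
subject's box drawn, or any callback); real e-mail/messenger clients
are out of scope.

## Synthetic scenes

The generator renders a two-segment capsule silhouette (torso+head and
legs; 80 px standing height, so inferior occlusion affects a distinct
lower region) over a static textured background, 320×240 at 8 Hz by
default — the resolution and frame rate the detector is designed for.
Subject texture is anchored to the body frame so optical flow has
trackable structure; gait adds a 1.5 Hz length bobbing, and lying
subjects wobble ±1° ("calm but not frozen"). Additive Gaussian pixel
noise defaults to σ = 2 grey levels. Perpendicular falls rotate the
body about the feet to 8° from horizontal over 0.75 s (the transition
duration is a free parameter with no external anchor); parallel falls
foreshorten the silhouette to a ratio-≈1 blob; sitting shortens it to
65%. Scripted nuisances: a chair that jumps position at t = 2 s, a
±25% illumination ramp, and a low-contrast blob that slowly expands
after a fall (the carpet scenario). Everything is a pure function of
the script including its seed; identical scripts give bit-identical
frames.

Ground truth records per frame the visible silhouette's bounding box
and orientation plus the hidden fraction, and labels every frame with
exactly one of NOT_FALL / FALL / OCCLUDED_FALL, the FALL interval
being the stable lying plateau.

**What passing the synthetic suite shows — and does not.** The suite
demonstrates that the chain of components is implemented coherently:
segmentation feeds tracking, features separate the scripted postures,
occlusion rules fire at the right times, and the debounce arithmetic
is exact. It does not demonstrate performance on real video: the
synthetic subject is a rigid capsule without articulated limbs,
clothing deformation, or perspective foreshortening; the background
has no TV, no moving curtains, no camera auto-exposure; shadows are
not cast by the subject. Reported suite metrics (e.g. 100%
sensitivity) are therefore statements about the implementation under
its study conditions, not field performance.

## Evaluation conventions

Scoring is per event. A fall interval with at least one fall alert
inside it ± 2 s grace (matching the alert delay) is a true positive;
stray alerts are false positives individually, and each non-fall
segment is one negative event, correct iff no stray alert lands in it.
The standard precision TP/(TP+FP) is used; the algebraically
inconsistent precision formula that sometimes appears in print
(TotalPositives/(TP+FN)) is not, since only the standard definition
reproduces the companion worked example (sensitivity 96%, specificity
97.6%, precision 96%, accuracy ≈ 97% from 24/25 caught falls and one
stray alert in 41 negative events).

## Problem sizes and numerical choices

The shipped experiment uses 7 training scenes (≈ 700 frames) and a
20-scene evaluation suite (≈ 2 200 frames) at 320×240/8 Hz; one full
run takes a few minutes on one CPU core. Degenerate inputs are handled
explicitly: empty masks give empty clouds, clouds under 5 points skip
pruning, a zero-span feature dimension maps to 0.5, zero-height
observations and non-finite measurements raise, and empty scenes
produce no tracks. Covariances are re-symmetrised after each update;
box height/width are floored at 1 px.

## Known limitations

Single subject per scene (the tracker is multi-track capable but the
generator and tuning are single-person); daylight scenes only; only
inferior occlusions; no walking-aid or pet confounders; the KNN
training distribution is generator-specific and must be rebuilt for
real deployments from labelled recordings.
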