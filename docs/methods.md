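# Methods

This note records the models implemented by the package, the parameter
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical choices that affect results.

## Evaluation protocol

Boxes follow the COCO convention: `(x, y, w, h)`, top-left origin,
continuous 0-based coordinates, area `w·h`. Matching is greedy and
one-to-one: detections are visited in descending score order (score ties
broken by input order) and each claims the unmatched ground truth with the
highest IoU, provided it reaches the IoU threshold (IoU ties go to the
lower ground-truth id). Precision is TP/(TP+FP), recall TP/(TP+FN).
Crowd-flagged ground truths are ignore regions: they are excluded from the
FN denominator, and an otherwise-unmatched detection overlapping a crowd
box at or above the threshold is dropped from the precision denominator
rather than counted as a false positive. Consequently
`tp + fp + n_ignored = #detections`; without crowd boxes the familiar
`tp + fp = #detections` holds exactly.

Average precision uses COCO 101-point interpolation: the mean over the
recall grid {0, 0.01, …, 1} of the maximum precision among operating
points at or beyond each recall level. An exact trapezoidal mode is kept
behind a flag for cross-checks. mAP averages AP over the ten IoU
thresholds 0.50–0.95. Recall at a precision floor (default 0.85) is the
best recall among the discrete PR points whose precision reaches the
floor — no interpolation between points, so the number is reproducible
from the curve alone. Size stratification uses the area rule: a target is
*small* iff `w·h < 40² = 1600 px²` (a `dims` mode requiring both sides
below the limit is available); when computing per-stratum recall, the
out-of-stratum ground truths become ignore regions so detections on them
do not poison precision, mirroring COCO's area-range handling.

## Attention energy (SimAM)

The energy assigns label −1 to the M−1 non-target neurons of a channel
and +1 to the target neuron t, and measures the ridge-regularised squared
error of the best linear transform. Solving ∂e/∂b = 0 and ∂e/∂ω = 0 gives

    ω_t = 2 (t − μ_t) / ((t − μ_t)² + 2 σ_t² + 2λ),
    b_t = −(t + μ_t) ω_t / 2,

with μ_t, σ_t² the leave-one-out mean and (population) variance, and the
attained minimum e*_t = 4(σ_t² + λ) / ((t − μ_t)² + 2σ_t² + 2λ). Note the
sign of ω_t is *positive* with this labelling; formulations that assign +1
to the distractors instead produce the negated ω with identical minimum
energy. The implementation was pinned to the argmin of the energy as
written, verified against Nelder–Mead minimization per neuron. A useful
parity: negating every neuron in the channel flips ω_t but leaves b_t
unchanged (both factors of b flip).

The *fast* variant substitutes the channel-wide mean and variance for the
leave-one-out statistics — exact in the M → ∞ limit, visibly different at
M = 2, and within 5% relative on 64×64 standard-normal channels. The
refinement step gates features with `sigmoid(1/e*)` (distinctive, low-
energy neurons get gains near 1; neurons at the channel mean are damped to
sigmoid(1/2) ≈ 0.622). λ defaults to 1e−4, the original SimAM choice;
statistics never cross channels. Degenerate cases: a constant channel has
e* = 2 exactly for any λ > 0, and λ = 0 on a constant channel is an error
(zero denominator).

## Correlation-filter tracker

The tracker is a baseline KCF on raw features: grayscale (BT.601 luma for
RGB, uint8 rescaled to [0, 1]), mean-subtracted, under a Hann window, on a
patch padded 1.5× around the target. Training solves the dual ridge
regression over all cyclic shifts in the frequency domain,
`α̂ = ŷ / (k̂^{xx} + λ)`, with a wrap-around Gaussian regression target of
width 0.1·√(w·h). The Gaussian kernel over all shifts is computed with a
single FFT cross-correlation; the bracket ‖x‖² + ‖z‖² − 2c(τ) is clamped
at 0 before exponentiation to guard round-off. Detection evaluates
`IFFT(k̂^{zx} ⊙ α̂)` and takes the wrap-aware peak, refined per axis by a
3-point quadratic fit (clipped to ±0.5 px). Defaults — padding 1.5,
kernel σ 0.5, target σ factor 0.1, λ 1e−4, learning rate 0.075 — follow
the published KCF configuration. Design restrictions: fixed scale, no HOG
features, replicate padding at image borders (avoids wrap artifacts where
the circulant model meets real borders). Mean subtraction makes the peak
response invariant to global intensity offsets. On a zero-variance patch
the model trains without error and yields a flat response map.

## Temporal fusion

For each current frame with a full look-back window (lookback_seconds ×
fps frames; 3 s default, fps is required configuration because the
interval cannot be converted to frames without it), the *keyframe* is the
window frame whose single best detection score is highest, ties to the
most recent frame. One tracker per keyframe detection is stepped
frame-by-frame to the current frame with online updates; a track whose
peak response falls below 0.25 is discarded as drifted. Surviving tracked
boxes carry score `source_score · 0.95^steps`: the paper of record for
this design gives no score model for propagated boxes, and exponential
decay makes fresh detections dominate ties, so fusion *optimizes* rather
than replaces the detector output. Fusion is greedy NMS (threshold 0.5)
over current-then-tracked candidates; with a stable sort this guarantees
current detections win exact ties. Tracked provenance is recorded per box.
Frames without a full window pass detections through unchanged. The
pipeline optionally takes a separate detection source for the look-back
window (`lookback_detections`), which models a slower high-quality pass
feeding the keyframe store while the current frame sees the fast degraded
detector.

A structural property worth noting: fusion can only add candidate boxes,
and NMS keeps the highest-scoring representative of each cluster, so
per-frame recall never decreases relative to the current detections alone.

## Annotation QC

Boxes strictly smaller than 5 px on either side are removed (a 5×5 box is
kept — the rule is "smaller than"). Crowd-flagged boxes represent dense
groups as a single region; they bypass the size rule, are tallied
separately, and downstream matching treats them as ignore regions rather
than per-individual ground truth. The filter is idempotent and the report
satisfies `n_input = n_removed_small + n_kept`. The size histogram bins by
area against squared side-length edges, consistent with the small-object
rule. Keyframe sampling is greedy: keep the first timestamp, then each
next frame at least `interval` seconds after the last kept one.

## Synthetic data

The generator emulates the statistics the pipeline is sensitive to, not
appearance: a static textured background (smoothed Gaussian noise — fixed
cameras over water/meadow), targets rendered as oriented ellipses whose
box-area distribution is a two-component mixture (43% below 40×40 px by
default, sides 8–39 px for small and 40–120 px for the rest), rigid
motion at 3 px/frame with occasional random direction changes and
reflecting frame borders. Each target carries fixed speckle texture that
translates rigidly with it, because the correlation tracker needs texture
to lock onto. Default analysed frame rate is 2 fps, so the 3-s look-back
spans 6 frames.

Two deliberate idealizations:

- **Targets are mutually exclusive.** The scene is planar — solid birds
  cannot interpenetrate — so objects bounce off each other on near-contact
  and ground-truth boxes never overlap. This keeps ground truth
  unambiguous under NMS-based evaluation (two overlapping true boxes would
  make even a perfect detector self-suppress). Real footage contains
  depth-induced box overlap that this generator does not model.
- **Occlusion is explicit.** Painting an occlusion rectangle suppresses a
  target's mock detection through a forced-miss flag rather than through
  image analysis, keeping fixtures deterministic.

Placement uses largest-first corner search on a jittered coarse grid with
whole-layout restarts; a size draw that cannot be packed into the frame at
all (≈1% of seeds at defaults, e.g. eight ~100 px targets) is rejected and
redrawn, a conditioning whose effect on the size mixture is far below the
statistical resolution of any test here.

The mock detector drops each annotation independently (miss rate),
jitters survivors (Gaussian, σ = 1 px default on center and size), scores
them Beta(8, 2) (optimistic but imperfect confidences), and adds
Poisson(0.5)/frame false positives scored Beta(2, 5). Point-mass score
models are available for identity-chain fixtures. Random draws are
consumed in a fixed per-annotation order so a forced miss does not shift
the random stream of other annotations.

What passing tests on this data do **not** show: robustness to appearance
change (posture, lighting), depth-overlapping flocks, camera motion,
compression artifacts, or detector failure modes that correlate across
frames. The fusion-recovery results quantify the temporal mechanism under
independent dropout, which is its best case.

## Problem sizes and numerical choices

Test and acceptance workloads use 30-frame, 10-object, 320×320 sequences
(ten seeds for the fusion-recovery comparison; 2000 boxes for the size-
fraction recovery), sizes at which the full chain runs in seconds per
sequence on one CPU while leaving every stage's behaviour visible.
Oracle comparisons use 100 random channels (M ∈ {2, 4, 16, 64}) for the
attention energy (≤1e−6 relative), 8×8 and 16×16 patches for the kernel
correlation (≤1e−8 absolute), and ≤20-detection instances for AP (≤1e−9
absolute). IoU of identical boxes is returned as exactly 1 (float
round-off in the rectangle arithmetic can otherwise land an epsilon on
either side of 1), and leave-one-out variances are clamped at 0 against
catastrophic cancellation. All stochastic tests run with fixed seeds;
the pipeline itself contains no randomness.

## Known limitations

- The KCF tracker has no scale adaptation or re-detection; long occlusions
  end tracks (by the response threshold) rather than recovering them.
- One keyframe serves the whole window. A per-object keyframe (tracking
  each object from the frame where *it* scored best) could recover more,
  but requires cross-frame object identity that the detection format does
  not carry, so it was left out.
- The evaluator is single-class; per-species metrics are out of scope.
- The attention operator is an offline analysis/visualization tool here;
  it is not wired into a trainable network.
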