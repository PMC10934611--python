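# Methods

## Problem and pipeline

`wanderlens` screens for cognitive impairment from ambient smart-home sensor
data alone. The premise, long established in the dementia-care literature, is
that indoor travel patterns carry diagnostic signal: cognitively healthy (CH)
residents mostly walk *direct*, efficient paths, while persons with dementia
(PwD) are enriched in *random*, *pacing* (back-and-forth) and *lapping*
(repeated loops) travel — the Martino-Saltzman taxonomy.

The pipeline has six stages:

1. **Ingestion.** CASAS-dialect event logs (`[date] time sensor_id value`)
   are parsed; activation edges (`ON`/`OPEN`/`PRESENT`) of motion (`M`),
   door (`D`) and object (`I`) sensors are joined with a sensor-position
   table into position records `<x, y, t>`. Deactivation edges carry no new
   positional information and generate no record.
2. **Noise reduction.** A single left-to-right pass drops any record whose
   implied speed from the last *retained* record exceeds `v = 15 m/s` or
   whose displacement exceeds `d = 5 m`. Comparing against the last retained
   record (rather than the raw predecessor) keeps the filter well defined
   and idempotent once a glitch is removed. A zero time gap with nonzero
   displacement is treated as infinite speed.
3. **Segmentation.** A locomotion episode ends when no sensor fires for
   strictly more than `Ts` seconds (default 60 s; 60–480 s is the
   interesting range). A gap of exactly `Ts` does not split. Fragments with
   fewer than 3 records cannot support a turn angle and are discarded (the
   count is logged). Episode counts are monotonically non-increasing in `Ts`
   for the raw gap-splits; after the <3-record discard the monotonicity can
   break, because tiny fragments may fuse into countable episodes.
4. **Visual encoding.** Each episode becomes a small RGB image (default
   130 × 100 px; the metric scale is fitted from the sensor table's bounding
   box plus a one-pixel margin). Steps are drawn with the canonical midpoint
   (Bresenham) algorithm; the path color is a linear blue ramp from
   (100, 150, 200) at rest to (200, 230, 255) at `v_cap = 3 m/s`, lighter =
   faster, with the most recent traversal's speed shade overwriting on
   repeated coverage. Per-pixel traversal counts drive line thickness,
   `min(count, 3)` px. Single-pixel markers are stamped last, in a fixed
   z-order (turn direction, door/object interaction, stationarity over 2 s,
   sharp angles ≥ 90°). All path-ramp colors keep BT.601 luminance above the
   0.5 binarization threshold so the walked path survives as foreground;
   red stationary and black sharp-angle markers fall below it and punch
   holes into the binary mask, which the topological features then see.
5. **Features.** From the binary + grayscale image pair, 15 connected-region
   features of the largest 8-connected component (area, fitted-ellipse axes,
   eccentricity, orientation, perimeter, circularity
   `(4πA/P²)(1 − 0.5/r)², r = P/(2π) + 0.5`, filled area, Euler number
   computed as objects minus 4-connected holes over the whole image,
   equivalent diameter `sqrt(4A/π)`, solidity, extent, max/mean/min
   intensity). From the RGB image, ORB keypoint descriptors quantized
   against a K-word k-means vocabulary (default K = 500; K = 50 in tests and
   the shipped evaluations for speed) into an L2-normalized histogram.
6. **Assessment.** An RBF-SVM (C = 0.7) — or naive Bayes, 5-NN, decision
   tree, or a 100-unit ReLU/Adam MLP (1000 epochs, batch 200) — classifies
   episodes CH vs PwD under leave-one-person-out (LOPO) cross-validation,
   with SMOTE balancing of the minority class inside each training fold.
   Per subject, the long-term diagnosis is the majority vote over episode
   predictions; ties resolve to PwD because a screening instrument prefers a
   false alarm to a miss.

## Design choices where the design was open

**Descriptor layer.** The visual-word front end is pluggable. SURF is
patent-encumbered and absent from common Python stacks, so the default is
ORB (oriented FAST + rotated BRIEF): free, deterministic, and robust to
scale and rotation. Trajectory images are sparse line drawings, so the FAST
threshold is lowered to 0.02 with a budget of 200 keypoints per image;
the stock threshold detects almost nothing on thin constant-color paths.
SIFT was evaluated and rejected: its difference-of-Gaussian detector finds
no keypoints on roughly two-thirds of these images.

**Vocabulary fitting.** k-means (fixed seed) on descriptors pooled over the
training images, subsampled to 5000 descriptors with a single
initialization; larger budgets were measured to be quality-neutral while
multiplying the cost of per-fold refits. By default the vocabulary is refit
inside every LOPO fold from training subjects only, so no test-image
structure can leak into the codebook; a shared-vocabulary mode exists and is
faster but optimistic.

**Block-wise standardization.** Before SVM/kNN/MLP fitting, the 15
region features — which mix pixel counts, degrees and unit-interval ratios —
are z-scored with statistics from the training split. The visual-word
histogram block is *not* z-scored: it is already L2-normalized onto a common
scale, and standardizing its sparse bins inflates rare-word quantization
noise to unit variance, measurably degrading the SVM (LOPO macro-F1 0.775
vs 0.830 on the default synthetic cohort). `scale_head=None` restores
whole-vector standardization.

**SMOTE inside the fold.** Synthetic minority vectors (`a + λ(b − a)`,
λ ~ U[0,1], b among the k = 5 nearest minority neighbours) are generated
after standardization, from training subjects only. Balancing before the
LOPO split would leak synthetic copies of test-subject structure.

**Turn-direction geometry.** "Center-ward" is defined as the outgoing
heading pointing within ±30° of the direction to the sensor layout's
centroid; otherwise the sign of the cross product of incoming and outgoing
step vectors separates left from right. Turn markers require a ≥30° heading
change so that ordinary path curvature is not flagged at every record.

**Canvas scale.** A fixed 0.1 m²-per-pixel scale on a 130 × 100 canvas
would imply an implausibly large home, so the scale is derived from the
sensor table's bounding box; a fixed-scale `CanvasSpec` remains available
for bit-exact fixtures.

**Euler number sign.** Objects minus holes, the standard definition: a
solid blob is +1, each enclosed hole subtracts one. Marker-punched holes in
the path mask therefore push the Euler number down, which is exactly the
signature pacing/lapping episodes leave.

## The synthetic smart-home

The simulator emulates the kind of deployment these systems target: a
single-resident apartment (10 × 9 m) with 52 ceiling PIR sensors on a 1 m
grid, 3 door contacts and 5 tagged objects. Each PIR is a binary presence
disk (radius 0.7 m, nearest sensor wins on overlap) that fires `ON` on entry
and `OFF` on exit — no re-triggering while the resident stays inside one
field. Residents walk piecewise-linear paths between waypoints at
N(0.8, 0.2²) m/s clipped to (0.1, 2.0) — well under the 15 m/s gate, so
clean traces survive preprocessing — with short exponential dwell pauses
(capped at 10 s, under every segmentation threshold). Episode mixtures
default to 90% direct / 10% random for CH subjects and 30% pacing /
30% lapping / 30% random / 10% direct for PwD subjects, about 12 episodes
per subject separated by 600–1200 s of inactivity.

What the simulator does **not** model: PIR physics beyond the disk
(sensitivity lobes, latency, missed detections), furniture and wall
occlusion, activities of daily living, multi-resident traces, and the
clinical heterogeneity of real cohorts, where the pattern mixture differs
per person and per time of day. Passing the synthetic end-to-end test
demonstrates that the pipeline's machinery — encoding, features, balancing,
fold hygiene, voting — recovers a class difference that is genuinely present
in the event streams; it does not certify clinical performance on real
smart-home data.

## Numerical details

- Timestamps parse to microsecond precision; kinematics use exact
  `datetime` differences.
- Zero-length steps inherit the previous step's heading; heading changes are
  wrapped to [0°, 180°].
- Binarization is strict (`luminance > 0.5`); BT.601 weights
  (0.299, 0.587, 0.114).
- Largest-component ties resolve to the smaller top-left bounding-box
  corner, row-major. An all-background image raises an explicit empty-region
  error; callers substitute an all-zero feature block with a warning.
- Nearest-word assignment breaks ties toward the lowest center index; images
  with no detectable keypoints get an all-zero histogram.
- Metric edge case 0/0 (e.g., precision with no positive predictions) is
  defined as 0.
- If fewer than K descriptors are pooled, K is clamped with a warning; zero
  descriptors across an entire training set is a fatal error.
- All randomness (simulation, SMOTE, k-means, classifiers) flows from
  explicit integer seeds; reruns with the same configuration are
  byte-identical on CSV/JSON outputs.

## Evaluation sizes

The shipped evaluations (test suite and `scripts/acceptance.py`) use the
default cohort of 40 CH + 10 PwD subjects (~530 episodes at Ts = 60 s) with
a 50-word vocabulary — large enough that LOPO folds are stable and the
law-of-large-numbers checks on the generator bind, small enough to keep a
full double evaluation (with and without SMOTE) around a minute.

## Known limitations

- Real CASAS streams interleave locomotion with activity noise and sensor
  faults that the disk-model simulator does not reproduce; published scores
  on that dataset are additionally sensitive to an unspecified subject
  selection, so they are not reproduction targets here.
- The stationarity detector sees only position records, so a resident who
  dwells inside one PIR field without re-triggering it produces no repeated
  coordinates and no stationary marker; dwell information below the sensing
  resolution is invisible to the whole pipeline.
- CRF features describe only the largest connected component; heavily
  fragmented paths (many marker holes) lose some mass to secondary blobs.
- The per-fold vocabulary refit makes histogram columns fold-dependent;
  this is the honest protocol, but it costs a little accuracy relative to a
  shared vocabulary and most of the discriminative power resides in the
  region features.
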