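# Methods

This note documents the models, parameters and design choices behind
`seasight`, and what the synthetic-data tests do and do not establish.

## The segmentation model

Sighting scenes are modeled as three region types with distinct color
balance: land (red/green dominant), sea plus marine animal
(blue-green to neutral), and sky (blue dominant). Two channel
differences capture this: `GMR = G − R` and `BMG = B − G`, each in
[−255, 255] for 8-bit input and linearly rescaled to [0, 1] as
`NGMR = (GMR + L)/2L`, `NBMG = (BMG + L)/2L` with `L = 255`. The
normalization exists because distance- and threshold-based rules
implicitly weight features by their range; on the unit scale one
threshold set works across images. `L` is fixed at 255 even for 16-bit
input, which is first rescaled into the 8-bit range.

Sea and animal are deliberately one segmentation class: the animal's
wet skin mirrors the surrounding water, so separating them by color
alone is unreliable. Disambiguation is deferred to region selection
and the descriptor classifier.

**Morphological closing** (grayscale dilation then erosion, square
11×11 structuring element) homogenizes each region before
thresholding. The window is a tunable (`window`, odd, ≥ 3); 11 is the
default because it is the smallest size that suppresses within-region
texture at typical sighting-image scales while preserving animal-sized
structures. Border handling is replicate padding — constant
borders stay constant, and no frame artifact is introduced by the
padding itself. Closing is idempotent and extensive (never decreases
a pixel), which the tests assert.

**Thresholding** assigns LAND where `value ≤ T_C1`, ANIMAL where
`T_C2a ≤ value ≤ T_C2b`, SKY where `value ≥ T_C3`. All comparisons
happen after rounding values to 4 decimals. This quantization is load-
bearing: threshold sets are specified at 4-decimal precision with
`T_C2a = T_C1 + 0.0001` and `T_C3 = T_C2b + 0.0001`, so on the
4-decimal grid the three bands tile [0, 1] exactly; without rounding,
values strictly between adjacent thresholds would fall into no class.
Shipped defaults: NGMR (0.4608, 0.4609, 0.5781, 0.5782) and NBMG
(0.4491, 0.4492, 0.5898, 0.5899), the 100-training-images sets, with
the full 5–100-image sweep available in
`THRESHOLDS_BY_TRAINING_SIZE`. These are configuration constants for
real sighting imagery, not quantities the package re-derives (their
training images are external); calibration re-derives thresholds for
any new corpus.

**Index fusion.** How the NGMR and NBMG decisions combine is a
genuinely open design point; two rules are provided. The default
`union` rule keeps agreed labels and lets ANIMAL win any disagreement
(recall-oriented: a pixel either index flags as animal is kept);
remaining land/sky disagreements resolve to the NGMR label, the
better-behaved index on land. The `and` rule requires both indices to
agree on ANIMAL (precision-oriented). Morphology and thresholding run
per index, before fusion, since the thresholds are defined on each
index's own smoothed image.

**Regions.** Candidate animal regions are maximal 8-connected
components of the ANIMAL label (4-connectivity available), filtered by
`min_size`, default 0.1% of the image area — small enough to keep any
plausible animal, large enough to drop speckle. Components sort by
size descending with ties broken by the smaller (top, left) bbox
corner, and the largest is the localization candidate. An empty
candidate list propagates to an absent location.

## Calibration

From class-pure training images (land / marine animal / sky), each
image is reduced to one statistic: compute the normalized index, close
morphologically, build a 256-bin histogram on [0, 1], and take the
modal bin — refined to the mean of the values inside that bin, so a
constant image of value v yields exactly v rather than a bin center.
Class statistics are averaged; the land/animal boundary is the
midpoint of the land and animal means, the animal/sky boundary the
midpoint of the animal and sky means, each rounded to 4 decimals, with
the inner band bounds one step (0.0001) inside. A per-image Otsu
statistic is available (`statistic="otsu"`) but the mode is the
default: Otsu assumes a bimodal within-image histogram that class-pure
crops do not have. Calibration fails loudly when the class means are
not ordered land < animal < sky — in that case no single band per
class can separate them.

`calibration_stability` re-runs calibration on seeded random
subsamples of the corpus at requested sizes and reports a tidy table,
for studying how few training images suffice.

## Localization

Interest points are scale-space maxima of the determinant of the
Hessian (scikit-image's `blob_doh`), the detector family SURF uses.
Defaults: scales σ ∈ [2, 32] sampled at 15 steps, DoH threshold
0.001, at most 200 keypoints. The scale ceiling of 32 px covers
objects up to roughly two-thirds of a typical region crop; the 15-step
sampling keeps scale quantization fine enough that rescaling an image
does not alias keypoints across scale bins (the scale-invariance smoke
test exercises exactly this). Each keypoint gets a dominant
orientation (sliding π/3 window over Gaussian-weighted gradient
responses within radius 6σ) and a 64-d descriptor: a 20σ×20σ
oriented patch, 4×4 subregions, each contributing
(Σdx, Σdy, Σ|dx|, Σ|dy|) of Gaussian-weighted derivative responses in
the rotated frame, L2-normalized. Extraction is fully deterministic.

Training aggregates each image's descriptors by their mean (variable
descriptor counts make raw summation dimensionally undefined), then
forms the class prototype as the mean of per-image aggregates and the
class weight `W_C` as the sum of their norms — the class's summed
descriptor mass. A class whose every image yields zero descriptors is
a training failure, reported as such.

Classification converts the squared Euclidean distance `M_C` between
the region aggregate and each prototype into the similarity
`S_C = 1/(1 + M_C)` and scores `R_C = (S_C / W_C) / Σ_k (S_k / W_k)`;
the argmax wins. The distance-to-similarity conversion is deliberate:
a literal "maximum of M/W" would select the *worst*-matching class, so
the maximum-score rule is applied to a similarity while the weight
normalization is kept; a literal minimum-distance mode
(`decision_mode="distance"`) is provided for comparison. Ties resolve
to the marine-animal class first (the method exists to find animals;
false positives surface in evaluation), then by class order.

The candidate ROI handed to the classifier is, by default, the
bounding-box crop of the *original* image with pixels outside the
region zeroed (`roi_mode="masked"`) — a binary segmentation mask
carries almost no scale-space structure, so features come from the
image data under the mask. The crop gets a 12-px zero margin so
boundary keypoints keep their full sampling neighborhood; without the
margin, detection near the crop edge differs systematically from
training patches and classification degrades badly. `bbox` (no
masking) and `binary` (the literal mask) modes are available.

`locate` chains the whole pipeline and emits bbox and centroid (x, y;
origin top-left) only for a marine-animal decision. `track_sequence`
maps `locate` over frames with no shared state — deliberately: the
method uses no temporal information, which keeps per-frame cost
constant at the price of robustness to occlusion and rapid change.

## Evaluation

TP/TN/FP/FN are counted per image from (located?, present?) pairs; the
five metrics follow the standard definitions, with 0/0 reported as
undefined (`None`) rather than 0. Reports round to 2 decimals for
display and keep raw values. `recall_curve` uses the standard
"detect iff score ≥ t" convention, under which recall is
non-increasing in the threshold; published recall-versus-threshold
plots sometimes show the opposite orientation (an ascending
convention), which this module documents rather than imitates — curve
values from such plots are never test targets here.

## Synthetic scenes

The generator emulates the geometry and color statistics of sighting
images: horizontal sky (top), optional land strip, sea below, animal
ellipse on the sea. Default 160×200 px — small enough that the full
50-scene end-to-end suite runs in seconds, large enough for an
11×11 closing and multi-scale keypoints to behave as on real images.
Default colors (R, G, B): sky (100, 160, 230), sea (60, 110, 155),
land (120, 90, 60), animal (90, 92, 96). These put the classes in the
required index order (land 0.441 < animal ≈ 0.505 < sky ≈ 0.62 on
NGMR) and — deliberately — place the *sea* above the calibrated
animal/sky boundary on both indices, so calibrated segmentation labels
sea as SKY and the animal component stands alone. This mirrors the
behavior on real sightings, where the published segmentations highlight
the animal rather than the whole ocean, and is what makes "largest
animal-band component" a meaningful candidate rule in the synthetic
world.

Texture is luminance-only mottling (equal increments in R, G and B;
Gaussian-correlated, length 5 px, per-class amplitude 4–14 gray
levels): it gives the keypoint detector structure without moving the
color indices at all. Chroma-affecting degradations are explicit:
global illumination shift, Gaussian blur (default σ 0.5) and
per-channel noise (default σ 2 gray levels). All randomness comes from
one integer seed split into substreams (background, animal shape,
distractors, noise), so frame sequences can share a background while
varying noise per frame. Degenerate specs (1-px animals, zero-height
sky) are permitted and exercised in edge tests. The distractor mode
places small (default 2.5 px radius) animal-colored blobs in the sky,
emulating birds; at the default size the 11×11 closing removes them,
so a distractor-only scene yields an absent location.

Training patches come in two styles: `flat` (class color + mottling,
for threshold calibration) and `roi` (for the animal class, an ellipse
on a black background, matching the masked-ROI crops the classifier
sees at detection time).

**What passing the synthetic tests shows — and does not.** The tests
establish that every algorithmic component is correct (exact oracles
for morphology and connected components, arithmetic identities for
indices and metrics) and that the pipeline is self-consistent: with
thresholds calibrated on the generator's classes, animals are found
within 5 px with mask IoU ≈ 0.95 in essentially all noise-free scenes.
They do not establish performance on real sighting imagery — real
scenes have waves, glare, haze, mixed-pigment animals and chroma
texture that the banded generator intentionally omits. Real-data
performance rests on the published evaluation, whose confusion
matrices the evaluation module reproduces exactly.

## Numerical choices, in brief

- 4-decimal rounding before threshold comparison (band totality).
- Replicate padding for morphology; `nearest` boundary mode for all
  gradient/sampling operations.
- Closing output clipped to [0, 1] against floating-point drift.
- Descriptor vectors L2-normalized; zero-norm vectors (flat patches)
  left as zeros rather than divided.
- Keypoints processed in a deterministic (scale, y, x) order; seeds
  below 2³¹ everywhere.
- Equal-size region ties: smaller (top, left) corner wins.
- Scene problem sizes: 160×200 scenes, 64×64 patches, 50-scene
  evaluation batches, 100-trial calibration-recovery batches — chosen
  so the full suite and the acceptance script each run in well under a
  minute on one CPU.

## Known limitations

- Multiple animals (or multiple birds) merge into one region — no
  instance counting.
- The classifier's prototypes are global mean descriptors; it
  separates the three scene classes but is not an individual-animal
  identifier.
- Recall-curve thresholds apply to the animal score margin; other
  scored quantities must be supplied by the caller.
- SURF proper (box-filter approximations, integral images) is not
  used; the implementation keeps SURF's detector principle
  (determinant of Hessian), descriptor layout and dimensionality, but
  computes responses with Gaussian derivatives. Descriptors are
  therefore not interchangeable with another library's SURF output.
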