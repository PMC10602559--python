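# Methods

## Scope and data model

The package analyses short fluorescence videos of the larval zebrafish heart:
stacks of T × H × W intensity frames in [0, 1] with a frame rate, nominally
2 s at 50 frames/s (100 frames) covering at least four cardiac cycles. The
observable chain is

    video  →  per-frame ventricle mask  →  area trace + rectangle axes
           →  cardiac parameters per larva  →  group-level screen scores.

All conventions are fixed once: 0-based frame indices, (row, col) pixel
coordinates, and pixels as unit squares (pixel (r, c) occupies
[r, r+1) × [c, c+1) with its centre at (r+0.5, c+0.5)). A single foreground
pixel therefore has a 1 × 1 minimum-area rectangle.

## Synthetic beating-heart simulator

No public dataset of labelled larval ventricle videos exists, so the
simulator is a first-class component: every training set, oracle test and
acceptance quantity is generated from it, with the truth known in closed
form.

A heart is an ellipse with end-diastolic semi-axes (a₀, b₀) whose axes
contract as a(t) = a₀(1 − c_a·s(t)), b(t) = b₀(1 − c_b·s(t)), where s(t) is a
raised-cosine waveform in [0, 1] at f = HR/60 Hz. Two choices deserve note:

- **Phase.** s is offset by a quarter period so the first end-diastole falls
  strictly inside the video. A maximum on frame 0 is not a local extremum of
  the sampled trace and would be invisible to any peak detector; the offset
  removes this artificial boundary case without changing any derived
  quantity.
- **Waveform.** The default raised cosine is smooth and symmetric; an
  "asymmetric" variant compresses systole into a configurable fraction of
  the cycle (default 0.35), mimicking the faster contraction / slower
  filling of a real beat. Ground-truth FAC/FS/HR are identical for both.

The mask is the exact rasterization of the ellipse (pixel foreground iff its
centre lies inside) *before* blur and noise; the image applies foreground /
background intensities, an optional antiphase atrium blob, Gaussian blur,
per-frame translation jitter of the whole heart (truth masks follow the
jitter), and additive Gaussian noise, clipped to [0, 1]. Closed-form truths:
EDA = π a₀ b₀, FAC = (1 − (1−c_a)(1−c_b)) × 100 %, FS = c_a × 100 % (or the
other axis if uneven contraction swaps which axis is longer), HR = the
specified bpm. Rasterized mask area matches π a b to well under 3 % for axes
≥ 8 px.

Defaults describe a healthy larva under the standard protocol: 96 × 96 px,
50 fps, 100 frames, 150 bpm, semi-axes (20, 12) px, 25 % contraction of both
axes, foreground 0.85 / background 0.10, noise SD 0.03, blur σ 1 px. These
were chosen once as plausible values for fluorescence imaging of this kind;
the original study reports no noise or size statistics, so they are not
calibrated to real data — passing tests demonstrate correctness of the
algorithms under these conditions, not performance on real microscopes.

The dataset-construction protocol mirrors standard practice: augmentation by
random rotation (bilinear for images, nearest-neighbour for masks, so masks
stay binary), horizontal/vertical flips, and a multiplicative
brightness/contrast gain drawn from [0.9, 1.1] applied to the image only;
a seeded 4:1 train/validation split (validation size floored, remainder to
training — 2125 items split 1700/425); and training-set expansion by
appending augmented copies (factor 3 turns 1700 into 5100).

## Segmentation

**ZVSegNet** is a U-Net variant assembled from:

- *Recurrent residual convolutional units (RRCU)*: each unit projects its
  input with a 1×1 convolution, then applies two stacked recurrent 3×3
  convolution layers — h ← relu(conv(x)), then h ← relu(conv(x + h)) with
  shared weights, unrolled t = 2 steps — and adds the projection residually.
- *Two-level skip fusion*: decoder level i concatenates the encoder feature
  at its own resolution and the next deeper encoder feature (upsampled),
  fusing two receptive-field scales per skip; the deepest decoder level has
  only its own-resolution skip.
- *Attention*: additive attention gates on every skip path (gated by the
  decoder feature at that resolution) plus squeeze-excitation channel
  attention after each encoder/decoder unit.
- *ASPP*: parallel 3×3 convolutions with dilations (1, 2, 4, 8) at the
  bottleneck, concatenated and fused 1×1.

Defaults: single input channel, base width 8, depth 3 (so inputs must be
divisible by 2³ = 8; inference pads edge-replicated and crops back). The
exact unrolling of the recurrence, the attention type, the dilation rates,
channel widths, loss and optimizer are design choices of this package — the
architecture family is specified only at the block level in the literature
it follows.

Training minimizes binary cross-entropy **on logits** plus soft Dice on the
probabilities, with Adam (lr 3·10⁻³), batch size 8, and global gradient-norm
clipping at 5. The logits form of BCE matters: with class-imbalanced masks
the network can collapse to all-background in the first epoch, where BCE on
clamped probabilities has vanishing gradient and training never recovers;
the logits form keeps gradient sigmoid(z) − t and recovers reliably across
seeds. The best-on-validation-loss model is returned. Inference binarizes at
0.5 (configurable) and keeps the largest connected component, since exactly
one ventricle is expected; input frames are min-max normalized per frame.

A classical baseline (`baseline_segment`) — per-frame Otsu threshold plus
largest connected component — serves as a deterministic, model-free oracle.
On noiseless synthetic videos it reproduces the rasterized truth exactly, and
it is invariant to positive affine intensity rescalings (hence to bit depth).

Evaluation: IoU, Dice, precision, recall, pooled over frames
(micro-averaged) by default with a per-frame (macro) mode exposed. Both
masks empty counts as perfect agreement; the identity DC = 2·IoU/(1 + IoU)
holds by construction and is asserted property-style over random masks.

## Cardiac parameters

The area trace (foreground pixels per frame) is smoothed with a moving
average of max(3, fps/20) frames, and extrema are detected with a prominence
threshold of 5 % of the trace's dynamic range (both exposed). ED peaks are
paired with the first following ES trough before the next ED; EDA/ESA and the
rectangle axes are averaged over these pairs (a global-extremum mode is
exposed). The contraction count used for heart rate is
max(#ED peaks, #ES troughs): a beat whose trough falls beyond the last frame
is still a beat, which is what manual counting gives; HR then follows the
cycles-per-video-length formula (a spanned-duration mode, cycle count between
first and last ED over their time separation, is exposed as `hr_mode`).
Cycles where the ED area is below the ES area are rejected and logged. A
flat or monotone trace yields a partial result with HR/FAC/FS/SV marked NaN
and an explicit "no heartbeat detected" status.

The minimum-area rotated rectangle treats pixels as unit squares: the
rectangle (any orientation) encloses all four corners of every foreground
pixel, computed by rotating calipers on the convex hull (shapely's
`minimum_rotated_rectangle`). Tests cross-check it against an exhaustive
0.5° rotation-grid search on random blobs. One caveat documented from
observation: for small rasterized ellipses the optimal rectangle may tilt
relative to the ellipse axes and under-read the long axis by a pixel or two;
axis-derived quantities (FS, SV) on ventricles below ~10 px semi-axis carry
correspondingly larger relative error, which is why recovery guarantees are
stated for ventricles of realistic size (semi-axes ≳ 12 px).

Stroke volume follows the ellipsoid-difference formula on the rectangle
axes. Its printed form is ambiguous about full versus semi-axes; the default
uses the axis lengths as printed, and `convention="semi-axis"` halves them
(prolate-spheroid volumes, exactly 1/8 of the printed form). A negative SV
is permitted but logged, as it flags ED/ES mis-detection.

## Heart-rate estimation

Traces are linearly resampled to 100 samples and standardized to zero mean /
unit variance (constant traces map to zeros). **HRNet** is a 3-layer 1-D CNN
(channels 8/16/16, kernel 5, two ×2 max-pools), an inception layer with
parallel kernels (3, 7, 15) of 8 channels each capturing peak structure at
several time scales, and a 3-layer MLP (64, 32, 1) on the flattened features
with a softplus output enforcing nonnegative bpm. Loss is MSE on bpm, Adam
lr 2·10⁻³, batch 32, 150 epochs, 4:1 seeded split. Loss, normalization and
resampling policy are this package's choices; the reference description
fixes only the three-part structure and 100-frame inputs.

The peak-counting oracle (cycle detection → cycles/duration × 60) is exact
on clean periodic traces up to whole-cycle quantization of the 2-s window
and is the standard the trained network is compared against. Evaluation
reports RMSE, MAE, Pearson r, and SD defined as the *population* standard
deviation of signed errors, so RMSE² = bias² + SD² holds exactly; r is
reported as NaN (undefined), never 0, when either side has zero variance.

## Screening

Rescue indices are computed on group means (the group-notation form of the
index), with a per-larva CSV → group aggregation path in the pipeline. Edema
enters as the group fraction of normal larvae, weighted equally with the six
continuous parameters (seven parameters total). Indices are not clamped by
default — a compound worse than the model scores negative, over-rescue
exceeds 1 — with `clamp=True` exposed. Parameters with no model-vs-control
signal (equal means) are dropped from both numerator and denominator with a
warning rather than zero-filled. Hits are strictly above the 0.7 threshold;
ranking is by descending score with lexicographic tie-breaks.

## Determinism and numerics

All linear algebra runs on a small float32 reverse-mode autodiff engine
(im2col convolutions with dilation, max pooling, nearest upsampling,
broadcasted arithmetic) written for this package and property-tested against
central finite differences. Everything is single-threaded numpy: fixed seeds
give bit-identical simulations, training trajectories and output CSVs
(floats written at 6 significant digits). Backward passes tear down the
computation graph as they consume it, and inference runs under a no-grad
mode, so memory stays flat over training.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the package's
own working sizes: segmentation training uses 200 labelled 64 × 64 frames
(4:1 split, 8 epochs, base width 8); heart-rate training uses 500 synthetic
traces spanning 60–240 bpm (150 epochs); the synthetic screen uses 7 groups
of 5 larvae at 96 × 96 × 100 frames. Full-scale protocol numbers (2125
labelled frames expanded to 5100; 296 heart-rate videos) are supported by the
same code paths and are exercised arithmetically in the split/expansion
tests.

## Known limitations

- The simulator renders a single convex ellipse; real ventricles are
  non-elliptical, partially occluded by the atrium, and show intensity
  texture from the myocardial wall. Results on synthetic data bound
  algorithmic correctness, not real-world segmentation accuracy.
- Axis measurements inherit minimum-area-rectangle quantization (about
  ±1 px per axis); FS and SV for very small ventricles are accordingly
  noisy.
- HR from cycle counting is quantized to whole cycles per video length
  (30 bpm resolution for a 2-s video); rates that are not multiples of the
  quantum are recovered to within one cycle, exactly as manual counting
  would be.
- The two networks here are small CPU-trainable configurations; no claim is
  made of matching the reference networks' reported validation metrics,
  which depend on their unreleased imaging datasets and weights.
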