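# Methods

## The resizing model

Let `I` be a single-channel image of size `W × H` and let the target
low-resolution size be `grid_w × grid_h` (from a linear rate `r`:
`grid_w = round(W·r)`, half-up). The image is decomposed as `I = H + B`
into a homogeneous part and a boundary part by a superpixel map with
exactly one superpixel per low-resolution pixel.

**Superpixel extraction (USEQ).** Initial superpixels are grid cells of
size `ceil(W/grid_w) × ceil(H/grid_h)`; the last cell along each axis
absorbs the remainder (and can be smaller; should a cell end up without any
pixels, the nearest non-empty grid neighbor acts as its donor everywhere a
value is needed). Color quantization histograms each cell's intensities
into `n_bins = 16` uniform bins over the intensity range; the dominant
color is the midpoint of the most populated bin (ties to the lower bin).
One MAP reassignment pass then moves each pixel `p` with intensity `I(p)`
from its superpixel `i` to the candidate

    argmin_{j ∈ {i} ∪ N(i)}  λ_s ‖p − c_j‖² + λ_c (I(p) − d_j)²

over the grid 4-neighbors `N(i)`, with centroids `c_j` and dominant colors
`d_j` from the quantization step. Ties prefer the current label, then the
lower index, so a constant image reproduces the grid exactly. The pass is
single-shot (no iteration) and the whole extraction is deterministic.

The native USEQ fourth step — merging small superpixels into visually
similar neighbors — is disabled by default because merging would break the
one-superpixel-per-low-res-pixel bijection the resizing framework needs; it
is available behind `refine=True` for standalone superpixel use, where it
returns a plain label image.

**Weights.** `λ_s = 1/(cell_w·cell_h)` and `λ_c = 1/255²` (more generally
`1/max_value²`). Both terms are thereby dimensionless: the spatial term is
≈1 one cell away from a centroid, the color term is ≈1 at full intensity
range. This keeps the behavior stable across resolutions and rates without
retuning. With these defaults a step edge of ≥~100 graylevels is captured
to within about one pixel; lower-contrast edges increasingly stay with the
spatial grid.

**Boundary classification.** A pixel belongs to `sp_i^B` iff one of its
4-neighbors carries a different superpixel label (Euclidean distance-1
contact); `sp_i^H` is the complement within `sp_i`. The image border itself
creates no boundary pixels: with a single superpixel the boundary set is
empty, and at rate 0.5 (2×2 cells) everything except the four image-corner
pixels is boundary — which makes the rate-0.5 round trip exactly lossless
for *any* image, since boundary pixels are restored verbatim.

**Downsampling.** `I(p_i^D) = mean{ I(p) : p ∈ sp_i^H }`, accumulated in
floating point and rounded half-up to the bit depth. Fallbacks: empty
homogeneous set → mean over all of `sp_i`; empty superpixel → value of the
nearest non-empty grid neighbor (lowest index on ties). The original
intensities of all boundary pixels are captured in the boundary store.

**Upsampling.** Labels: every pixel of `sp_i` takes the low-res label of
`i`. Images: homogeneous pixels take the low-res value, boundary pixels are
restored from the store. The stored intensities are *not* used for label
upsampling — they are graylevels and carry no class information; the
superpixel's label applies to its boundary pixels too. An optional low-res
background mask zeroes background superpixels on image upsampling; it is
only applied when supplied explicitly, since background cannot be inferred
from intensities alone.

Consequence used by the tests: if an image is constant on every superpixel
(edges coincide with superpixel boundaries), the round trip is bit-exact —
homogeneous means reproduce the constants and boundary pixels are copied.

**Baseline resizers.** Nearest, bilinear and bicubic interpolation use the
center-aligned coordinate mapping `x_in = (x_out + 0.5)·W_in/W_out − 0.5`
(scipy `map_coordinates`, spline orders 0/1/3), clipping and rounding
half-up. Bilinear and bicubic downsampling apply a Gaussian anti-aliasing
prefilter with `σ = (factor − 1)/2` per axis, as mainstream resize
implementations do; nearest neighbor never filters, and no filter is
applied when upsampling or at identical sizes (all methods are exact
identities at the same size). Without the prefilter, order-3 resampling
aliases badly at strong downsampling and drops below bilinear quality,
which misrepresents what any practical bicubic resize does.

## Segmenters

**Threshold reference.** Lung fields are air-filled and dark, so `label =
I < t` (default `t = 110`, the midpoint of the phantom's lung/body
contrast) is an exact segmenter for noise-free phantoms and a deterministic
stand-in wherever the pipeline, not the classifier, is under study.

**Encoder–decoder.** A compact SegNet-style network implemented directly
on numpy arrays: `n_stages` encoder blocks (3×3 conv, batch norm, ReLU,
2×2/stride-2 max pool storing per-window argmax indices) mirrored by
decoder blocks (index-driven unpooling, 3×3 conv, batch norm, ReLU), then a
3×3 conv to `N = 2` classes and a per-pixel softmax. He-initialised from a
seeded generator; inputs are scaled to [0, 1]; sides not divisible by
`2^n_stages` are reflect-padded and cropped back after prediction.
Training minimises unweighted per-pixel cross-entropy with Adam
(β₁ = 0.9, β₂ = 0.999) on batches drawn without replacement by a seeded
generator, so runs are bit-reproducible. A non-finite loss aborts with a
diagnostic rather than training on.

Two profiles exist. The *toy profile* — `n_stages = 3`, channels
(8, 16, 32), 64×64 inputs, batch 4, lr 5e-3, ≤500 iterations — is what the
test suite trains; it overfits eight downsampled phantoms to Dice ≈ 1.0 in
under a minute on one CPU. The *full profile* (five stages, channels up to
512, 256×256 inputs, lr 5e-4, 40,000 iterations) is reachable through the
same parameters but is not exercised by the tests. Kernel sizes and channel
widths are package choices; nothing in the architecture depends on them
structurally.

## Post-processing

Foreground components are ranked by pixel count under 8-connectivity and
all but the two largest erased (ties at the cutoff go to the component
appearing first in row-major scan order; fewer than two components are all
kept). Enclosed background regions — 4-connected regions not touching the
image border — are then filled. Keep-then-fill order matters: a hole that
filling would absorb cannot rescue a small component's rank. The
8/4-connectivity pairing is the standard complementary choice that avoids
topological paradoxes. The composite is idempotent, never leaves more than
two components, and never leaves holes.

## Phantoms

`make_phantom` renders two elliptical lungs (default semi-axes 80×42 px on
a 256×256 canvas, centers jittered by a few pixels, tilt 2–6° outward) at
intensity 40 on a body of 180, optionally a dark distractor ellipse below
the lungs and a bright lesion ellipse inside the left lung, then adds
clipped Gaussian noise. Ground truth is the union of the lung ellipses
only — the distractor is excluded and the lesion counts as lung — so the
distractor/lesion phantom reproduces exactly the failure modes
post-processing corrects, and correction recovers the truth bit-exactly in
the noise-free case. Mask rotation in the augmentation path uses
nearest-neighbor resampling to keep labels binary; images rotate
bilinearly.

The generator validates its invariants (lungs inside the frame and
disjoint, distractor outside the lungs, lesion inside one) and is
deterministic per seed. What the phantoms do *not* model: ribs, clavicles,
mediastinum and soft-tissue texture, exposure gradients, and the air
border around the patient. Passing tests therefore demonstrate the
resizing framework's boundary preservation and the pipeline's mechanics,
not clinical segmentation accuracy on radiographs.

## Metrics and conventions

- Fractions (DSC, sensitivity, specificity, Jaccard) come from pixel
  confusion counts; a zero denominator yields 1 (empty-vs-empty is
  perfect). `DSC = 2J/(1+J)` holds to 1e-12.
- Boundaries are inner boundaries: foreground pixels with a 4-neighbor
  background pixel or on the image border.
- MHD (directed, the default) averages over ground-truth boundary points
  the Euclidean distance to the nearest prediction boundary point; the
  symmetric option returns the max of the two directed means. MBD is the
  mean of the two directed means, with an optional mm-per-pixel spacing.
  Nearest-point queries use a k-d tree and are test-verified against
  all-pairs brute force. Empty boundaries raise rather than return a
  sentinel.
- PSNR uses `MAX_I = 2^bit_depth − 1` (not the observed maximum, so values
  compare across images); a zero-MSE pair reports `math.inf`, and averaging
  helpers exclude infinite values while counting them separately.

## Problem sizes

The test suite and the acceptance script work at the sizes a single CPU
handles comfortably while still exercising every code path: 256×256
phantoms for pipeline quality (10 phantoms, rate 0.25), 128×128 noisy
phantoms for the PSNR comparison (20 phantoms × 3 rates × 4 methods),
64×64 piecewise-constant images for exact-reconstruction checks (50 images
× 3 rates), 1,000 random mask pairs up to 32×32 for metric/oracle
equivalence, and the toy training profile above.

## Known limitations

- The MAP pass is single-shot by design; edges cutting deeper than about
  half a cell into a low-contrast region are not fully recovered, which
  bounds mask upsampling accuracy at very aggressive rates.
- Superpixel counts above 65,535 cannot be serialized to the 16-bit PNG
  sidecar format (the in-memory path has no such limit).
- The encoder–decoder is CPU-oriented and makes no attempt at the
  throughput of a GPU framework; the full-scale profile trains, but slowly.
- Grayscale only; multi-channel resizing and multi-organ labels are out of
  scope (the mask machinery itself is N-class capable).
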