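# lungseg

Boundary-preserving superpixel resizing for high-resolution lung field
segmentation.

Chest radiographs are large (2048×2048 and up), so segmentation models
almost always run on a downsampled copy and the low-resolution mask is
upsampled back. With plain interpolation both steps blur object boundaries:
the downsampled image mixes lung and body intensities along edges, and the
upsampled mask carries staircase artifacts. `lungseg` implements a resizing
framework that avoids both problems by resizing *along superpixels*:

1. **USEQ superpixels.** The image is partitioned into exactly
   `grid_w × grid_h` superpixels — one per low-resolution pixel — by
   spatial quantization (a regular grid), color quantization (dominant
   intensity per cell) and a single non-iterative MAP reassignment pass that
   snaps superpixel boundaries onto image edges. Each pixel `p` in
   superpixel `i` moves to the candidate `j` among `i` and its grid
   neighbors minimising
   `λ_s‖p − c_j‖² + λ_c (I(p) − d_j)²`,
   with centroid `c_j` and dominant color `d_j`.
2. **Downsampling `F_D`.** Each superpixel `sp_i` splits into a boundary
   set `sp_i^B` (pixels 4-touching another superpixel) and a homogeneous set
   `sp_i^H`. The low-res pixel value is the mean of `I` over `sp_i^H`, so
   edges never bleed into the low-resolution image; the original intensities
   on `sp_i^B` are stored.
3. **Segmentation** runs at low resolution — a deterministic
   intensity-threshold reference or a compact SegNet-style encoder–decoder
   (conv → batch norm → ReLU → 2×2 max pool with stored argmax indices,
   mirrored by index-driven unpooling, per-pixel softmax).
4. **Upsampling `F_U`.** Every pixel of `sp_i` receives the low-res label of
   `i`; for images, homogeneous pixels take the low-res value and boundary
   pixels are restored from the store — edges return exactly where they
   were.
5. **Post-processing** keeps the two largest 8-connected components (the
   lungs) and fills enclosed holes.

The evaluation suite implements DSC, sensitivity, specificity, Jaccard,
modified Hausdorff distance (MHD), mean boundary distance (MBD) and
round-trip PSNR (`20·log₁₀ MAX_I − 10·log₁₀ MSE`).

Because real radiograph datasets cannot ship with the package, a phantom
generator produces chest-like test images: two dark elliptical lungs on a
bright body, optionally a dark distractor blob outside the lungs and a
bright lesion inside one (exactly the artifacts post-processing exists
for), plus Gaussian noise and ±10° rotation augmentation.

## Worked example

```python
import numpy as np
from lungseg import (LungFieldPipeline, evaluate_pair, make_phantom,
                     roundtrip)
from lungseg.synthetic import default_spec

image, truth = make_phantom(default_spec(size=256, seed=42))

pred = LungFieldPipeline(rate=0.25).predict(image)   # threshold reference
rep = evaluate_pair(pred, truth)
print(f"DSC {rep.dsc:.4f}  MHD {rep.mhd:.3f} px  MBD {rep.mbd:.3f} px")

for method in ("useq", "bicubic", "nearest"):
    _, p = roundtrip(image, 0.25, method)
    print(f"{method:8s} round-trip PSNR: {p:.2f} dB")
```

prints

```
DSC 0.9979  MHD 0.108 px  MBD 0.117 px
useq     round-trip PSNR: inf dB
bicubic  round-trip PSNR: 27.82 dB
nearest  round-trip PSNR: 24.44 dB
```

The pipeline segments at a quarter of the linear resolution yet the
full-resolution mask misses the true lung boundary by about 0.1 px on
average. The noise-free phantom is piecewise constant with edges the
superpixels adhere to, so the superpixel round trip reconstructs it
bit-exactly (infinite PSNR) while bicubic and nearest interpolation blur or
misplace the lung edges (finite PSNR, nearest worst).

The same operations are available from the shell:

```
lungseg synth --n 20 --size 256 --seed 7 --out data
lungseg run --image data/phantom_000.png --rate 0.25 \
            --segmenter threshold:110 --out mask.png
lungseg compare --data data --rates 0.125,0.25,0.5 --segmenter threshold:110
lungseg evaluate --pred preds/ --truth truth/
```

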