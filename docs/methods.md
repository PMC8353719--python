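# Methods

## Model

The package treats a grayscale image purely through its brightness
histogram. With `N` pixels over `L` gradations and counts `c_k`, the
normalized spectrum is `p_k = c_k / N` (exactly summing to 1 up to float
accumulation, observed < 1e-15 for L = 256) and the square sides are
`s_k = √p_k`. The transform is the orthogonal, axis-aligned placement of
those squares, in descending area order, inside a square container of
area 2. Existence is guaranteed by the packing theorem for squares of
total area 1 in a square of area 2; the shelf construction used in its
proof is the algorithm here, so the implementation and the guarantee
coincide. No brightness correction or equalization is applied anywhere:
the histogram is the measured object.

Underlying assumptions: the image is single-channel with integer values
in `[0, 2^b − 1]`; spatial structure is deliberately discarded (two images
with equal histograms have identical transforms); comparisons between
images are meaningful only at equal gradation count and identical
colormap/render settings.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| gradations `L` | inferred from bit depth (256 for 8-bit) | – | the three clinically common depths are 8/10/14 bits |
| container side | `√2` | container units | the area-2 theorem's container |
| render size | 450×450 | pixels | reference output dimensions |
| render mode | `antialiased` | – | see Rendering below |
| diff gain | 10 | – | reference contrast amplification of the subtraction image |
| diff offset | 128 | 8-bit counts | encodes signed differences around mid-gray |
| colormap | `bluered` | – | injective, content-independent; see below |
| background | white | – | squares are unstroked; outlines are not part of the model |

## Ordering and ties

Descending order by area is required; the tie rule is not. Ties are
broken by ascending gradation index (a stable sort on negated fractions),
because bit-identical reproducibility of layouts and renderings is a core
guarantee and any content-dependent tie rule would break it. Zero-count
gradations yield zero-area squares; they are parked at the end of the
ordering and skipped by the packer — packing degenerate squares is
meaningless and would only cost time.

## Packing

Next-fit shelf packing with square-height shelves: squares fill the
current shelf left to right; the shelf's height is its first (largest)
square's side; a square that would overrun the container width opens a
new shelf immediately below. The container origin is top-left with y
downward, matching raster orientation. The area budget check uses a
1e-9 tolerance since `Σ c_k / N` is exact only in infinite precision;
geometric comparisons use 1e-12. A shelf overflow is impossible for a
descending sequence of total area ≤ 1; the packer still asserts the
height bound at runtime and raises an internal error rather than emit an
invalid layout. `validate_layout` re-checks everything by brute force
(O(n²) pairwise interior disjointness, containment, ordering, area) and
is used as the independent oracle in the property suite.

## Colormap

Colors are a pure function of `(L, scheme)` and never of image content,
so transforms of different images are comparable. The default `bluered`
scheme ramps the red channel up and the blue channel down with the
gradation index, with a mid-peaked green ramp. An 8-bit hue-style sweep
alone can produce at most ~1.5k distinct colors, so for `L > 256` the
gradation's low-order bits are folded into the low bits of the green
channel; distinct gradations then map to distinct 24-bit colors for every
supported depth (injectivity is property-tested at L = 2, 256, 1024,
16384). Any matplotlib colormap name is also accepted for nicer figures,
without the injectivity guarantee.

## Rendering

Default rasterization is exact area-coverage anti-aliasing: each output
pixel blends square color and background by the square's geometric
coverage of that pixel, computed in closed form per axis. A one-pixel
edit of an `N`-pixel source moves a side by order `1/(2 s N)` container
units — around 1e-6 for the reference image — which vanishes entirely
under center sampling but always perturbs coverage. Detection therefore
runs on the retained float pre-quantization buffer; the 8-bit image is a
view. `nearest` mode (center sampling, half-open square edges) exists to
mimic hard-edged print figures; the two modes agree exactly on pixels
interior to one square. Subtraction operates on the float buffers by
default; whether quantization should precede subtraction is genuinely
open, so both paths exist and float-first is the default because it is
the more sensitive one.

## Perturbations

Pixel "removal" acts on the pixel multiset, not on the raster shape: the
histogram is the only downstream consumer, and multiset semantics make
the data-loss percentage `removed / total × 100` exact. A removed column
of the 945×1327 reference image is 945 pixels = 0.075% (2 s.f.), a row
1327 = 0.11%, one pixel < 0.0001%. Oblique segments are traced with the
standard integer line-stepping (Bresenham) rule, each crossed pixel
removed once. Random dot deletions draw from an explicit seed recorded in
the report; sequential deletions compare each state to its immediate
predecessor, so every report covers exactly one lost pixel. The detection
criterion is the float-buffer max-abs difference; the gain-amplified
quantized diff is produced for visualization.

## Registration

Pose differences between acquisitions are modeled as a 2D similarity
(uniform scale, rotation, translation). The least-squares fit is closed
form: center both landmark sets, take the rotation angle from the
symmetric/antisymmetric parts of the cross-covariance, the scale from the
projection onto that rotation, the translation from the centroids. This
replaces external stereo-photogrammetric machinery because, for
superimposing exported 2D tomogram bitmaps, displacement + rotation +
scale is exactly the required model; the implementation is cross-checked
against scikit-image's Umeyama estimator in the tests. Warping uses
inverse mapping with background 0 outside the frame. Nearest-neighbor
interpolation is the default because it preserves the brightness value
set; bilinear resampling invents intermediate values and thus perturbs
the histogram the pipeline measures, so selecting it logs a warning.

## Synthetic data

The fixture generators produce (a) images with exactly prescribed
histograms (counts dealt into a flat array, seeded shuffle, reshape), so
reference arithmetic such as "5963 of 1,254,015 pixels at gradation 125"
is reproducible bit-exactly; (b) linear gradient ramps with closed-form
histograms; (c) random spectra as multinomial draws over symmetric
Dirichlet weights (10^4–10^6 pixels), mimicking the rational fractions
`c_k / N` of real histograms; and (d) uniform random images. All are pure
functions of their parameters and seed. They emulate histogram structure
only — no anatomy, noise model, or spatial correlation — so passing tests
demonstrate the transform's arithmetic, geometric and sensitivity
guarantees, not clinical performance on real tomograms.

## Problem sizes

The property sweeps use 1000 random 256-gradation spectra for packing
validity and 100 random 200×200 images for single-pixel sensitivity;
both are comfortably past the point where failures, if any, would
surface, and the full suite runs in well under a minute.

## Known limitations

- The transform discards all spatial information by construction; it
  detects distribution changes, not where they occurred.
- Quantized 8-bit TMIs of a one-pixel edit can be identical; only the
  float buffers guarantee detection.
- JPEG sources are accepted but flagged: lossy decoding already perturbs
  the histogram.
- ROI vertex files are this package's convention for zone-of-interest
  input; boundary pixel centers count as inside.
- Registration assumes in-plane similarity; out-of-plane rotation of the
  anatomy between acquisitions is not modeled.
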