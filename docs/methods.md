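# Methods

## Color model

All pipeline arithmetic happens in CIE LAB, reached from 8-bit RGB through
CIE XYZ with the classic linear matrices

```
X = 0.412453 R + 0.357580 G + 0.180423 B        R =  3.240479 X − 1.537150 Y − 0.498535 Z
Y = 0.212671 R + 0.715160 G + 0.072169 B        G = −0.969256 X + 1.875992 Y + 0.041556 Z
Z = 0.019334 R + 0.119193 G + 0.950227 B        B =  0.055648 X − 0.204043 Y + 1.057311 Z
```

and the companding f(t) = t^⅓ for t > t₀, else a·t + 16/116, with
δ = 6/29, t₀ = δ³ ≈ 0.008856 and a = 1/(3δ²) ≈ 7.787037 — the unique
linear branch matching the cube root in value and slope at t₀.

Three deliberate conventions:

- **No gamma companding.** 8-bit values are scaled by 1/255 and used
  linearly. This is *not* sRGB; converters such as `skimage.color.rgb2lab`
  will disagree numerically. The package is self-consistent under its own
  convention, and the correction's guarantees (chromaticity conservation,
  planar exactness, round-trip fidelity) are convention-independent.
- **Reference white = row sums of the forward matrix** (≈ 0.950456, 1.0,
  1.088754). This forces RGB white → (100, 0, 0) exactly, which is the
  anchor the whole method leans on ("background should be L\* = 100").
- **Inverse fz.** The reverse transform uses fy = (L\*+16)/116,
  fx = fy + a\*/500 and **fz = fy − b\*/200**: the last is the expression
  that actually inverts the forward b\* = 200(fy − fz); a chain through fx
  would not, and forward∘inverse here round-trips to 1e-9.

The printed matrices are rounded, so the matrix pair is not an exact
inverse: the RGB↔XYZ round trip is good to ~1e-4, which is below half an
8-bit count — full RGB→LAB→RGB round trips move no 8-bit channel by more
than one count. Intermediate values are never clamped; RGB is clipped to
[0, 1] and L\* to [0, 100] only on write-out, to avoid compounding clamp
errors across pipeline stages.

## Illumination mask geometry

Inputs: four source points C1..C4 inside the image, no three colinear
(triangle-area tolerance 1e-9 px²), each carrying a deficit
m = reference − L\* (reference defaults to 100).

1. **Pair lines.** For each of the 6 pairs, the infinite line through the
   two points is clipped to the border rectangle x ∈ [0, W−1],
   y ∈ [0, H−1]. If both points lie on the same border, they serve as
   their own intersections. The deficit at each intersection is the 1-D
   linear extension of the pair's deficits along the line (signed
   projection parameterization).
2. **Border profiles.** On each border, every pair of intersection points
   with distinct positions defines a linear extension over that border;
   the profile is the unweighted mean of all such extensions (pairs at
   coincident positions are skipped — their extension is undefined). A
   border with fewer than two distinct intersection positions falls back
   to the least-squares plane through the four source deficits evaluated
   along that border; for planar fields this coincides with the exact
   answer, so the fallback is seamless in the regime the method targets.
3. **Interior.** At pixel (x, y) the mask is the mean of the linear
   interpolation in y between top(x) and bottom(x) and the interpolation
   in x between left(y) and right(y).

Properties worth stating precisely:

- **Planar exactness.** If the deficits are samples of a plane
  m(x, y) = a + bx + cy, every stage reproduces the plane exactly (each
  operation is an affine map that fixes affine fields), so the mask equals
  the plane at every pixel (verified to 1e-6 on 256×256, observed ~1e-14).
- **Not an interpolant in general.** For deficits *not* consistent with a
  single plane, the pairwise averaging does **not** reproduce the four
  anchor values at the source points (errors can be large when two
  intersection positions nearly coincide and their extension has a steep
  slope). This is inherent to the averaging construction, not a bug; the
  method is an estimator for near-planar fields, which is the documented
  shape of the artifact. The implementation is therefore cross-checked
  against an independent loop-based oracle of the same geometry (1e-9 on
  random configurations) rather than against an anchor-interpolation
  property that does not hold.
- **Application.** L\*out = clip(L\* + (factor/5)·mask, 0, 100) with
  integer factor 1..5. The deficit is *restored* (added), which is what
  maps background to the reference and makes output brightness monotone
  non-decreasing in the factor; a\*/b\* are copied bitwise. The linear
  factor/5 scaling is the simplest monotone mapping with factor 5 = full
  restoration.

### Automatic source-point selection

White candidates are pixels with L\* ≥ 90 (tunable). The image is split at
floor(W/2)/floor(H/2); boundary pixels belong to the right/bottom
quadrant. Per populated quadrant: the candidate with minimal Euclidean
distance to the centroid of that quadrant's candidates, ties broken by
row-major scan order (deterministic). Per empty quadrant: each found point
is reflected across the image's vertical/horizontal center lines as needed
to land in the empty quadrant; the (rounded, clipped) centroid of the
reflections becomes the synthetic point, and its deficit is the mean
deficit of the found points. The resulting set must still pass the
colinearity check; a degenerate outcome raises rather than guessing.

## Nuclei enhancement

Unsharp masking restricted to hematoxylin: the L\* plane is convolved with
a normalized Gaussian kernel (default 3×3, σ = 3, sampled at integer
offsets from G(x,y) ∝ exp(−(x²+y²)/2σ²)), the blurred plane is clamped to
[0, 100] (kept in floating point — "quantized" is read as range clamping,
not integer rounding, to preserve precision), and detail = L\* − blur.
Where b\* < 0 **and** |detail| > threshold (default threshold 0, so all
detail passes), L\*out = clip(L\* + factor·detail) with integer factor
1..12; everywhere else, and on a\*/b\* everywhere, the image is returned
unchanged. Convolution uses replicate-edge padding to avoid rim
artifacts. Enhancement composes with correction in whatever order the
caller chooses (typically after it) but does not require it.

## Statistics

`channel_stats` reports mean, unbiased (n−1) variance, and a 256-bin
histogram per LAB channel; `display_scale=True` first maps to the 0–255
convention of common editors (L\*·255/100; a\*, b\* + 128; clamped) so
reported b\* means are comparable with 8-bit histogram readouts.
`variance_f_test` computes F = s₁²/s₂² with df (n₁−1, n₂−1) and the
two-sided p = min(1, 2·min(P(F ≤ f), P(F ≥ f))) via the F distribution
(regularized incomplete beta under the hood), rejecting at α = 0.05 by
default. Pixels are treated as independent observations; spatially
correlated image data makes this optimistic, which is documented rather
than corrected — the test is a like-for-like comparison convention, not a
calibrated spatial model.

## Synthetic phantoms

A phantom is a white 8-bit canvas with randomly placed elliptical
cytoplasm patches (base RGB (240, 150, 140), per-object jitter ±10 counts)
each containing a concentric smaller nucleus ellipse (base (70, 85, 160),
same jitter). The bases are chosen so that, under this package's linear
conversion, cytoplasm satisfies b\* > 0 and L\* < 90 and nuclei b\* < 0
across the whole jitter range — the color-gating assumptions are true by
construction and verified by test. Four corner patches (side
max(3, min(H,W)/16)) are kept tissue-free so every quadrant retains true
white pixels; generation fails loudly if the image is smaller than 16 px a
side or if less than 5 % of pixels remain white. Degradation adds a known
field (≤ 0 everywhere) to the clean L\* in LAB and re-quantizes to 8 bits;
planar, mildly quadratic and uniform fields are supported, with defaults
α = −0.02, β = −0.015 L\*/px (≈ 9 L\* maximum loss on 256×256 — strong
enough to be clearly visible, mild enough that unstained pixels stay above
the L\* ≥ 90 detection threshold everywhere). All randomness flows from a
single explicit seed; identical arguments give bit-identical phantoms.

What the phantoms do *not* emulate: tissue texture, stain variability
beyond color jitter, optical vignetting, chromatic illumination effects,
sensor noise, JPEG artifacts. Passing recovery tests therefore
demonstrates correctness of the estimator under its planar-field model and
robustness to 8-bit quantization — not performance on arbitrary real
slides, where the field may deviate from planarity and white areas may be
scarce or impure.

## Problem sizes and numerical choices

The test suite and acceptance script use 16×16 grids for oracle
equivalence (100 random configurations), 256×256 for planar exactness and
the 20-phantom recovery study, 1000 random pixels for color round trips,
and 2000 replicates of n = 500 for F-test calibration — sizes at which
every property is already sharply decided (planar error ~1e-14 against a
1e-6 bound; recovery RMSE ~0.08 against 0.5/1.0 bounds). Geometric
coincidence tolerances are 1e-7 px; colinearity tolerance 1e-9 px²;
degenerate inputs (duplicate points, empty white set, zero-variance
samples, grayscale files) raise typed exceptions rather than warning.

## Known limitations

- Quadratic or higher-order illumination fields are only approximated;
  the recovery guarantee is exact-planar. For the mild quadratic fields in
  the test suite the correction still reduces error substantially.
- The four-point scheme extrapolates aggressively when two border
  intersections nearly coincide; with validated, well-spread points (the
  auto-selector's quadrant construction encourages this) the effect is
  not observed.
- Only additive L\* correction is provided; chromaticity shading (colored
  illumination) is out of scope.
- The F-test's independence assumption over pixels is optimistic (see
  above).
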