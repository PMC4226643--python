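# Methods

This note documents the models, conventions and design choices behind
`taxofeat`, and what the synthetic benchmark does and does not show.

## Coordinate and intensity conventions

Rasters are numpy arrays in row-major `(row, col)` order. Wherever the
classical formulas are written over `(x, y)`, `x` is the column index and
`y` the row index; a pixel has unit area. Grayscale intensities live in
[0, 255] and become float64 after filtering; masks are boolean.

## Preprocessing

The chain is: background removal → luminance grayscale
(0.299 R + 0.587 G + 0.114 B) → 3×3 mean filter → 3×3 median filter
(both reflect-padded) → Otsu binarization → contour → skeleton. Texture
descriptors read the *denoised grayscale restricted to the mask*;
geometric and moment descriptors read the binary mask.

**Background removal.** Specimen photographs in collections are taken
against a roughly uniform background, so segmentation is driven by a
background-intensity model: all pixels outside a rectangle assumed to
contain the specimen (default: the frame inset by 2 px per side) estimate
a background mean and standard deviation; pixels deviating by more than
3σ are foreground, then closed (disk radius 2), hole-filled, and cleaned
of components under 16 px. A pre-segmented mask can be supplied to bypass
the stage entirely, which is also how the test suite gets bit-deterministic
features. An empty result raises rather than returning a silent all-zero
mask. The method assumes a unimodal background and a specimen whose
interior differs from it by more than the background noise; it does not
handle cluttered scenes or multi-specimen frames.

**Binarization.** Otsu's threshold, with foreground polarity decided by a
border-majority vote: the intensity class holding most frame-border pixels
is background (specimens sit in the interior). A constant image has no
separating threshold and raises.

**Skeletonization.** Zhang–Suen two-subiteration thinning run to a fixed
point (hence idempotent). One deviation from the textbook parallel scheme:
deletion candidates are pre-screened in parallel but re-validated against
the current raster before removal. Fully parallel deletion annihilates
2-px-wide structures (a bare 2×2 block vanishes entirely); the sequential
re-check makes the thinning topology-preserving — every 8-connected
component of the input survives — which the property tests assert over
thousands of random blobs.

## Geometric descriptors

Perimeter is the *boundary-pixel count* (foreground pixels with a
background 8-neighbor, frame border counting as background). This is the
definition used by the historical morphometric systems this package
follows, not an arc-length estimate; it overestimates the length of
diagonal boundary, so the compatibility C = 4πA/P² of a digital disk
converges to ≈ 0.62 rather than 1. An optional `arc_length=True` mode
measures the sub-pixel 0.5-level boundary polyline instead and puts the
disk's C near 1; it exists for comparison and is off by default.

Compactness is defined as the exact reciprocal of compatibility. Since a
rounded division can make `C * (1/C)` miss 1.0 by one ulp, Co is nudged to
the neighboring float whose product with C is exactly 1 — the two features
are definitionally reciprocal and the stored values honour that.

Solidity uses the convex hull of foreground *pixel centers*, rasterized so
boundary ties count as inside (`convex_hull_image(offset_coordinates=False)`).
Filled convex digital shapes therefore have solidity exactly 1. Note a
degenerate consequence: a 5-pixel plus sign's center-hull contains exactly
its own 5 centers, so solidity is 1; the concavity penalty only appears at
larger sizes.

Masks with several components are measured as a union by default;
`largest_component=True` restricts to the biggest.

## Texture descriptors

First-order statistics are the mean and variance of the histogram of
masked gray values (the variance formula is the standard Σ(x−μ)²h(x)).
Second-order statistics come from a gray-level co-occurrence matrix at a
single offset: distance 1 along the −45° diagonal, i.e. `(Δrow, Δcol) =
(+1, +1)` in image coordinates, counting ordered pairs whose *both* pixels
lie in the mask, without symmetrization. Intensities are quantized
uniformly over the masked min–max range into L = 16 levels by default
(configurable, and recorded in the trained model file since features
depend on it); quantization is range-relative, so the features are
invariant to adding a constant to the image. Entropy uses the natural
logarithm (configurable base).

Because the offset is a fixed direction, the four co-occurrence features
are *not* invariant under 90° grid rotation for arbitrary textures — the
offset maps to (+1, −1). They are invariant whenever the texture carries
the same pair statistics in both diagonal directions (e.g. mirror-symmetric
texture), which is how the rotation-invariance test is constructed; the
geometric and moment features are rotation invariant unconditionally.

## Moment descriptors

Raw moments m_pq = Σ x^p y^q I(x,y) are computed over the mask (binary
weighting by default; grayscale weighting optional), central moments via
the standard translation identities, to order 3. For binary and integer
input the computation is exact: integer raw moments and `Fraction`-valued
central moments, so the unit tests compare against a brute-force
double-loop oracle with `==`, not a tolerance.

Normalized central moments are exposed with the exponent γ = (p+q)/2
(p+q ≥ 2). Note that standard texts use 1 + (p+q)/2; with γ = (p+q)/2
the second-order n_pq are *not* scale-free, so the first Hu invariant is
computed from the standard normalization,

    hu1 = (u20 + u02) / u00²,

which is what makes it invariant to translation, rotation and scale, as
the invariance suite verifies on digital disks (r = 16 vs 48, drift
< 0.1%). A raw-moment reading m20 + m02 is available behind
`hu1_mode="raw"` for comparison with older systems that used it; it is
not translation invariant.

The two affine moment invariants are the classical ones:

    ami1 = (u20·u02 − u11²) / u00⁴
    ami2 = (u30²·u03² − 6·u30·u21·u12·u03 + 4·u30·u12³ + 4·u21³·u03
            − 3·u21²·u12²) / u00¹⁰

Every numerator term of ami2 is degree-4 in the third-order central
moments (scaling like r²⁰, matching u00¹⁰) — a variant sometimes seen in
print drops the u03 factor from the second term, which breaks the
homogeneity and with it scale and affine invariance, so it is not used.
ami2 vanishes identically on point-symmetric shapes; its discrete-grid
stability is therefore tested on blobs with strong third-harmonic
structure, where shear by 0.3 moves it by ~3%.

## The classifier

A one-hidden-layer perceptron with logistic activations on both layers,
15 inputs, h hidden units, m outputs (one per species, one-hot targets).
Training is online stochastic gradient descent on E = ½‖y − t‖², one
update per pattern presentation; "generations" counts presentations, not
epochs (matching the 50,000–140,000 magnitudes practical for tables of a
few hundred to a few thousand patterns). Presentations draw from a
freshly shuffled order each pass. Weights and biases initialize uniform
(−0.5, 0.5) from the config seed; training is bit-reproducible given
(data, config). Momentum is available but defaults to 0 (plain descent).

Inputs are z-scored with training-set mean/sd, stored in the model and
re-applied at prediction time. This standardization matters: the raw
descriptors span many orders of magnitude (pixel areas next to
probabilities next to 10⁻¹⁰-scale invariants), and sigmoid units saturate
immediately on unscaled inputs. A feature constant in training (sd = 0)
is centered and given unit scale. The analytic backpropagation gradients
are validated against central finite differences (norm-relative error
~10⁻¹⁰ at ε = 10⁻⁵) in the tests and the acceptance script.

Prediction reports the argmax species (ties to the lowest index), the raw
sigmoid outputs, the 0.5-thresholded binary vector, and a flag when no
output clears 0.5. Models serialize to a single versioned JSON container
(weights, scaler, label map, config).

## Evaluation protocol

Train/test splits are stratified per species — each species contributes
`round(f·n)` training samples, clamped so both sides keep at least one —
because a split that loses a species entirely makes its test specimens
unclassifiable by construction. Every reported success rate is the mean
over a configurable number of seeded repeats (default 3), with the seeds
recorded in the report. The neuron sweep trains one model per hidden
width under the same policy and continues past individual failures.

## Synthetic benchmark

Each species is a parametric silhouette: an ellipse with semi-axes (a, b)
whose radius is modulated by Fourier harmonics k = 2–4, filled with
mean intensity + axial sinusoidal stripes + Gaussian noise (σ = 6), on a
uniform background (205 ± 2). Individuals jitter the species parameters
(axes σ = 0.6 px, amplitudes σ = 0.008, intensity σ = 3.5), and are
randomly rotated (full circle) and translated (±5 px) on a 96×96 canvas.
The continuum area πab(1 + ½Σamp²) is an analytic oracle for the
rasterized masks; ground-truth masks let segmentation be scored (IoU ≥ 0.9
against the pipeline on defaults).

The default family (`default_specs`) spreads 10 species over decorrelated
grids of axes (18–28 × 10–17 px), boundary waviness, interior brightness
(70–160) and stripe frequency — "moderate separation": distinct species,
overlapping individual distributions. A `separation` knob scales every
between-species difference (0 collapses the family to one species);
`confusable_pair` clones a species with a single-axis offset delta,
emulating congeneric species that differ in one subtle character.

Benchmark sizes were chosen as the smallest that exercise the full
protocol meaningfully: 10 species × 30 individuals for the split protocol
(h = 60, lr = 0.1, 50,000 presentations — the plant-collection training
configuration), and 2 × 30 for the confusability sweep (h = 15, 15,000
presentations — a 2-class problem needs far less capacity). At these
settings the 80/20 split identifies ≥ 98% of held-out specimens, all four
splits sit at 99–100% with the expected weak upward trend in training
fraction, and the confusability sweep runs ~50% at delta = 0 (chance),
~90–97% at delta = 2 px (≈3σ of the axis jitter) and 100% at delta = 8 px.

What passing this benchmark shows: the descriptor pipeline preserves the
information that separates the generating parameters, and the trained
network recovers it from realistic-scale samples. What it does not show:
performance on real photographs — the generator has uniform backgrounds,
no pose/illumination variation, no occlusion, and species that differ in
exactly the parameters the features measure. Accuracy on real collections
depends on photographic standardization and on how phenotypically close
the species are; the confusability sweep makes that degradation explicit
in the one dimension it models.

## Numerical details and degenerate inputs

- Empty masks, constant images (no Otsu threshold), single-pixel masks
  (no co-occurrence pair) and single-species training sets raise
  `ValueError` with specific messages rather than degrading silently.
- The GLCM of a constant region puts all mass at one diagonal cell
  (entropy 0, homogeneity 1).
- `sigmoid` is computed branch-wise to saturate without overflow at any
  finite input.
- Feature CSVs are written at %.17g so read(write(t)) is bit-exact
  (`float_precision="round_trip"` on read); malformed files report the
  offending column or line.
- The synthetic generator resamples a jittered individual up to 100 times
  if its parameters degenerate (axis ≤ 2 px), then raises.
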