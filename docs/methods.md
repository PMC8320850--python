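# Methods

This note records the models, conventions and numerical choices behind
`vtphantom`, and what the synthetic experiments do and do not demonstrate.

## The phantom model

The phantom is a single mid-sagittal slice represented as per-frame binary
masks for six regions — maxilla, mandible, epiglottis, velum, tongue and a
catch-all head region — rendered with uniform intensities on a zero
background.  Uniform regions are deliberate: they make aliasing, blurring
and ringing introduced by an acquisition scheme directly visible and
quantifiable, at the cost of not modelling tissue texture or MR relaxation
(intensities are abstract scalars in [0, 1], not derived from T1/T2).

Default intensities: head 0.5, mandible/maxilla 0.6, epiglottis 0.7,
tongue 0.8, velum 0.9 (configurable).  The default target resolution is a
256 x 256 matrix over a 300 mm square FOV at 30 fps.  Note the two spatial
knobs are independent: published speech-phantom work quotes a 1.719 mm
pixel alongside a 300 mm / 256 matrix combination that actually implies
1.172 mm; the package exposes FOV and matrix separately and does not
resolve that discrepancy.

### Procedural anatomy

`anatomy.generate_anatomy` builds a stylised head from ellipses and
rectangles: a skull ellipse, an oral airway channel open to the anterior
image border (the mouth), a vertical pharyngeal airway whose posterior
boundary is the pharyngeal wall, and the five articulator regions.  Two
motion classes are emulated:

- **velopharyngeal closure**: the velum flap's tip-to-wall gap follows a
  clipped sinusoid per cycle, `gap = clip(1.25 sin(pi tau) - 0.25, 0, 1)`
  scaled to a peak of 6% of the matrix — zero (contact, 8-connected to the
  wall) for roughly the first and last 6% of each cycle, giving a sustained
  closure plateau of several frames at 30 fps;
- **tongue advancement**: the tongue ellipse translates anteriorly by
  `excursion * sin(2 pi t / T)` pixels.

The seed perturbs the skull semi-axes by about one percent (distinct
subjects); all motion is deterministic.  Masks are made disjoint at
construction by the same priority rule used downstream, and exactly
partition the nonzero image support — that exactness is what makes
segmentation and reconstruction errors measurable.

What the generator does **not** emulate: anatomical shape detail, partial
volume and coil shading, susceptibility dropout, off-resonance phase, or
through-plane motion.  Tests passing on this phantom show the pipeline's
algorithms are correct and well-conditioned; they do not show that
segmentation thresholds or Dice levels transfer to acquired images.  One
concrete consequence: the piecewise-uniform phantom reconstructs from
Nyquist radial sampling with ~11% RMSE where real vocal-tract images give
roughly twice that, so a fixed 5% noise floor produces a larger *relative*
RMSE change here (~15%) than on acquired data (a few percent).

## Segmentation

Frames are enhanced with a binary Canny edge map scaled to
`edge_weight * max(frame)` (default 0.2).  Canny uses sigma 1.0 with
hysteresis thresholds from the gradient-magnitude histogram (high = 90th
percentile, low = 0.4 x high), all configurable, since only the algorithm
and the 0.2 weighting are fixed by convention.

The head mask is `frame > threshold` (Otsu by default) with
below-threshold components classified: border-connected components remain
background (the mouth opening makes the airway border-connected); enclosed
components are filled as signal voids unless marked by a user "airway
seed" point — needed e.g. for the nasopharynx, which becomes an enclosed
air pocket whenever the velum seals.  Articulator masks are the Hadamard
product of the per-frame head mask with a fixed user ROI polygon
(rasterised by the pixel-centre even-odd rule, `polygon2mask`); the head
region is the remainder.

## Mask optimisation and interpolation

`clean_mask` removes components below `min_component_px`, applies closing
then opening with a disk of `radius_px`, and fills interior holes.
`resolve_overlaps` applies `mask AND NOT union(higher priority)` in the
fixed order maxilla > mandible > epiglottis > velum > tongue > head —
rigid structures outrank mobile ones and the catch-all head always loses;
the order is configurable per series.

Temporal interpolation thresholds linear blends of signed Euclidean
distance transforms: `d(M) = EDT(~M) - EDT(M)` (negative inside, boundary
included by `d <= 0`), interpolant `{(1-a) d(A) + a d(B) <= 0}`.
Endpoints are exact by construction; a pure translation's midpoint lands
within a pixel of the geometric midpoint.  An empty side is assigned a
large positive constant distance (4 x the grid size) so objects shrink to
extinction rather than erroring.  Optical-flow or spline warping is
deliberately not used — distance-transform blending cannot smear, it can
only produce a binary shape.  Upsampling by `factor` yields
`factor*(T-1)+1` frames with native frames hit exactly; spatial
resampling nearest-neighbour-samples the signed distance at target pixel
centres and re-thresholds, preserving binarity.

## Fourier conventions and the gridding NUFFT

All modules share one convention: centred arrays (DC at index `N//2`),
image coordinates `x = index - N//2`, k in cycles/pixel in [-0.5, 0.5),
forward kernel `exp(-i 2 pi k . x)`.

The NUFFT uses Kaiser–Bessel convolution gridding: oversampling 2, kernel
width 8, Beatty shape parameter, and an apodisation profile computed as
the inverse DFT of the integer-sampled kernel — this makes the scale
self-consistent (on-grid samples agree with the FFT to machine-level
aliasing error, ~1e-8 relative) without any calibration factor.  Off-grid
worst-case error is ~1e-7 relative against brute-force summation, well
inside the 1e-3 contract.  The adjoint spreads with the same kernel, so
forward/adjoint pass an inner-product identity test to 1e-12.

## Trajectories and density compensation

- Cartesian: N lines on the centred grid, line-major ordering.
- Blipped EPI: the Cartesian grid with odd-indexed lines' kx offset by
  `line_shift` fractions of the grid step.  Reconstructing these samples
  *as if* on the nominal grid reproduces the uncorrected odd/even
  misalignment, whose alternating-line phase error creates the N/2 ghost.
- Radial: uniformly rotated diameters (golden angle deliberately not
  used), N samples per spoke, auto spoke count `ceil(pi N / 2)` — the
  azimuthal Nyquist criterion at the k-space edge.
- Spiral: Archimedean interleaves (default 16 at N=256, scaled with N)
  with radial pitch `n_interleaves * dk` per turn (composite pitch dk) and
  along-arc sample spacing bounded by 0.9 dk, evaluated at the step end so
  the bound holds while the radius grows.

Voronoi density compensation treats the normalized square as the periodic
Nyquist cell: points are tessellated together with their eight +-1
replicas, so every cell is bounded and the areas tile the square exactly —
which also makes full-grid weights exactly uniform, where clipping to a
hard square boundary would halve the cells of edge samples.  Duplicated
points (the shared radial centre) split their cell equally.  By default
weights are normalised to sum to 1.  For disc-coverage trajectories
(radial, spiral) `Trajectory.with_dcf()` instead keeps quadrature-true
areas clipped to the sampled disc (their sum is the covered fraction,
pi/4): normalising them to 1 would inflate reconstructed intensities by
4/pi and hand the unsampled corners' area to edge cells, which measurably
biases region intensities; with disc clipping the corners act as the
band-limit they physically are.

## Multi-coil model, SENSE and GRAPPA

Coil sensitivities are analytic: centres equally spaced on a ring of
radius 0.55 N pixels (just outside the FOV), Gaussian magnitude falloff of
width 0.4 N, a smooth phase advancing 0.25 cycles across the FOV diagonal
with distance from the coil, and pixelwise sum-of-squares normalisation to
1.  Exact maps are used by SENSE by default — map calibration from
low-resolution data is out of scope — so noise-free SENSE errors measure
conditioning, not map error.

Undersampling keeps every R-th phase-encode line starting at row 0 (`N/R`
lines regardless of ACS size); the centred ACS block is additionally
acquired and stored separately for calibration.

SENSE is the classical pixelwise unfold: the replica weights of the
sampling comb are computed numerically from the inverse DFT of the row
mask, the `n_coils x R` system per reduced-FOV pixel is solved by batched
(optionally Tikhonov-damped) least squares.  `R > n_coils` raises an
error, or warns and applies heavy regularisation when explicitly allowed.

GRAPPA calibrates, per missing-line offset, a linear kernel from 2
acquired ky neighbours x 3 kx columns x all coils to the missing samples
(defaults; kernel configurable), by least squares on the ACS block with
Tikhonov damping `1e-6 x mean diagonal` of the normal matrix.  k-space
edges use truncated neighbourhoods (indices clamped to the acquired
lattice) rather than circular wrap.  Acquired lines and the ACS block are
restored verbatim (data consistency); coils are combined by root sum of
squares.

## Evaluation

RMSE is reported per frame as a percentage of the *reference* frame's
intensity range (scale-free; recorded in every report; asymmetric under
swapping reference and test by construction).  When frame rates differ,
only common temporal points are compared: a low-rate frame aligns by
default with the last 30 fps source frame that contributed to it
("last" alignment; "centre" available).

The N/2 ghost ratio is the energy of the image where the N/2-shifted
support lands on background, divided by in-support energy — zero for a
ghost-free image, and exactly the replica energy ratio for a two-replica
image.

The qualitative flags ("velum and tongue discernible?", "aliasing
artefacts?") are operator-entered; the automated surrogate for the first
is a per-region recovery Dice: the reconstruction is thresholded at half
the region's nominal intensity and compared with the truth mask over the
region's 2-px-dilated vicinity excluding other tissue regions.  This
penalises organ signal loss and artefactual fill-in of adjacent airway
(the velopharyngeal gap failure mode) while treating contrast between
*tissues* as a separate, intensity-assignment question — a global or
nearest-level threshold is either degenerate (every region's
half-intensity is below the lowest tissue level) or unsatisfiably strict
(adjacent levels differ by 0.1, less than normal Gibbs ringing).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the dynamic experiments at
a 128 matrix (static frames for trajectory studies, 60 frames at 30 fps
for rate sweeps, 3 frames for parallel-imaging sweeps) and the structural
design numbers at the 256 target; these sizes exercise every code path at
full numerical fidelity while keeping a laptop-scale runtime.  All
randomness (anatomy jitter, noise) flows from explicit seeds; the
acceptance script derives every stream from its `--seed` argument.

## Known limitations

- 2D single-slice only; no off-resonance/phase maps, no T1/T2 signal
  model, no gradient-hardware constraints (slew/amplitude), no partial
  Fourier.
- SENSE/GRAPPA are implemented for uniform Cartesian undersampling;
  radial/spiral and temporal (k-t) parallel imaging are out of scope.
- GRAPPA quality on the synthetic phantom is better than on acquired data
  (exact sum-of-squares-normalised maps, no map error, low phantom
  complexity); coil-count and ACS *trends* transfer, absolute RMSE values
  do not.
- The labelled segmented frame rates {15, 8, 4, 2} fps correspond to
  segment counts {2, 4, 8, 15} of a 30 fps series, i.e. true rates
  {15, 7.5, 3.75, 2}; labels are rounded to integers.
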