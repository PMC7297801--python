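# Methods

## The measurement model

A giant unilamellar vesicle imaged at its equatorial confocal plane is a
thin circular rim.  The package models the rim's radial cross-section as a
Gaussian of width `rim_width` (default 2 px): a diffraction-limited image
of a bilayer much thinner than a pixel.  In a lectin channel the scene is

* free lectin in solution outside the vesicle at intensity `S` (lectin is
  applied outside; intact vesicles exclude it, so the lumen sits at the
  background offset, not at `S`),
* a rim whose centerline intensity is `(1 + c) · S`, where `c` is the
  binding contrast for the lipid phase at that angle (`c ≥ −1`).

The membrane-marker channel carries rim signal only: bright on
liquid-disordered (ld) arcs and dim on liquid-ordered (lo) arcs for a
BODIPY-type ld-partitioning marker (defaults 150 and 37.5 a.u., a 4:1
partitioning).  Which phase the marker labels is a configuration flag
(`marker_phase`), since other markers partition into lo.

The binding efficiency is defined as `BE = (I_rim − S)/S`.  The
subtraction is what anchors the statistic: a lectin that cannot bind gives
a rim equal to the solution, hence BE exactly 0; a plain ratio would give
1 there.  Being a ratio of intensities, BE is invariant under any positive
rescaling of the channel (laser power, detector gain).

## Synthetic scenes

The simulator renders the analytic field at pixel centers, then applies a
Gaussian PSF (`psf_sigma`, default 1 px), Poisson shot noise on the
photon-scaled signal (`poisson_scale`, default 5 photons per a.u. —
typical confocal photon budgets put hundreds to thousands of photons on a
bright rim), additive Gaussian read noise (default 2 a.u.), and clips at
zero.  One `numpy` generator seeded from the scene's single integer seed
drives everything, so a seed fully determines the image.  With the default
noise the rim SNR is ≈ 26 at contrast 0.5 and higher above.  Scenes whose
rim bands (radius ± 3·`rim_width`) overlap are rejected: their ground
truth would be ill-posed.  Angles are counter-clockwise from +x with y
pointing down; pixels are 0-based, origin top-left — shared by every
module.

Cell scenes place rectangular cells on a grid in a 3-D stack; a seeded
fraction (`labeled_fraction`, default 0.1, emulating 1:10 dilution of
receptor-positive cells into a wild-type monolayer) carries apical
membrane voxels at `ap_intensity` (default 70) and basolateral + lateral
wall voxels at `bl_intensity` (default 10), a 7:1 apical preference of the
magnitude seen for StxB on polarized epithelia.  Label masks are emitted
for receptor-positive cells only; isolation (no other labeled cell within
2 µm of the footprint) is computed from those masks.

What the simulator does **not** emulate: membrane undulations, tubular
invaginations, photobleaching, spectral crosstalk, out-of-focus light,
non-circular vesicles, and realistic cell shapes.  A green test therefore
establishes correctness of the measurement chain under the stated optical
model, not robustness to every real-microscope artifact.

## Rim statistics: `max` vs `fit`

The per-bin rim intensity is reduced from radial samples (0.25-px grid,
bilinear interpolation) in a band of half-width 3 px around the detected
radius, with 360 bins (1° resolution) by default.

* **`max`** (default): the radial maximum.  It tolerates sub-pixel
  detection error (the peak is found wherever it is), but it has two known
  biases: bilinear interpolation attenuates the sampled peak by up to
  ~8% depending on where the circle crosses the pixel grid, and a maximum
  of noisy samples is biased upward by roughly the local noise sigma.  For
  box-plot-level comparisons between conditions this is immaterial; for
  absolute contrast recovery it is not.
* **`fit`**: a matched-template amplitude.  The rim center radius and
  width are estimated once per GUV from a Gaussian least-squares fit of
  the angular-mean marker radial profile; a Gaussian template and a step
  base (lumen level inside, free exterior level per bin) are rendered on
  the pixel grid and pushed through the same bilinear sampler as the data,
  so model and data share one discretization.  Per bin, step height and
  rim amplitude are solved by linear least squares; the bin intensity is
  exterior + amplitude.  Linear in the data, hence unbiased under
  Poisson/Gaussian noise; on noise-free, PSF-free scenes it recovers the
  simulated contrast to well under 1%.

Monte-Carlo validation (100+ seeded noisy scenes, contrasts 0.5–10, SNR ≥
10, PSF off) shows `fit` bias within ±1.2% and per-scene errors below 3%.
With the PSF enabled, any rim statistic underestimates the *pre-blur*
contrast by the thin-rim attenuation factor
`rim_width / sqrt(rim_width² + psf_sigma²)` (≈ −11% at the defaults);
recovering the pre-blur amplitude would require deconvolution, which is
out of scope, so recovery claims are stated for the PSF-free regime and
relative comparisons elsewhere.

## Detection and the solution reference

Detection runs a circular Hough transform (radius range 10–40 px, absolute
normalized accumulator threshold 0.25) on Canny edges of the marker
channel.  Candidates are greedily suppressed if their disk overlaps a
higher-scoring one (ties broken toward the larger radius), then refined:
per-angle radial peaks (parabola sub-sampling) are fit with an algebraic
least-squares circle, giving centers good to a few hundredths of a pixel
on clean scenes.  QC flags — border-touching, mutually overlapping rim
bands, radius below the minimum, saturated rim pixels — exclude a GUV from
quantification without hiding it from the output.

The free-solution reference is the per-channel **median** over all pixels
outside every detected disk dilated by 5 px: the median resists bright
debris and undetected small vesicles.  For a Poisson-dominated exterior
the median sits below the mean by ~1/(3·`poisson_scale`) a.u., a < 0.1%
effect at the defaults.

## Phase segmentation

The marker angular profile is split by two-cluster 1-D k-means with
centers initialized at the 25th/75th percentiles — fully deterministic, no
random restarts.  The GUV is called `uniform` when the bright/dim cluster
mean ratio is below `min_contrast_ratio` (default 2; chosen so a 4:1
marker partitioning with moderate noise is always separable while
crosstalk-level modulation is not) or either cluster holds under
`min_arc_fraction` (5%) of bins.  Labels are smoothed by a circular
majority filter (5 bins) and bins within 1 bin of a boundary are excluded
from per-phase means, because the PSF mixes phases at domain edges.  On a
uniform GUV all bins carry the marker's own phase label; a single profile
cannot distinguish an all-ld from an all-lo vesicle, so per-phase values
are only reported for the phase present.

## Cell polarity

Membrane masks are an explicit input (the original analyses used custom
unpublished segmentation code, so the mask contract is the stable
interface).  Per experiment the AP/BL readout is the ratio of means across
isolated cells — not the mean of per-cell ratios — matching how such
polarity ratios are computed from per-condition mean values.  Conditions
are compared with a paired two-tailed t-test across experiments; an
all-zero difference vector returns (t = 0, p = 1), and a zero-variance
nonzero difference vector is degenerate and returned as NaN with a
warning.  Summaries with fewer than 50 measured cells are flagged
(`low_n`) rather than rejected.

## Reporting

Condition summaries are median, 25th/75th percentiles (linear
interpolation between order statistics — the dialect is recorded in the
table metadata because dialects differ) and min/max whiskers.  Pairwise
comparisons default to the two-sided Mann–Whitney U test (exact for small
tie-free samples via scipy's policy) with Holm adjustment across the
family; Welch's t is available where a location test on means is wanted.
Undersized groups (< 3 values) are flagged in the output, never silently
dropped.

## Numerical choices and edge cases

* Radial sampling step 0.25 px; bilinear (order-1) interpolation
  everywhere — higher orders overshoot at the rim and break the
  non-negativity of intensities.
* k-means and every simulator draw are seeded; pipelines are byte-
  deterministic given config + seed, and every output CSV carries a hash
  of the resolved configuration.
* Degenerate inputs raise typed errors: empty exterior mask (no solution
  reference), rim band outside the image, flagged detections, empty bin
  subsets, solution ≤ 0, < 12 angular bins for segmentation, overlapping
  or empty cell masks.
* Config validation (pydantic, `extra="forbid"`) rejects unknown keys
  before any computation runs.

## Known limitations

* No deconvolution: absolute contrasts under PSF blur are attenuated (see
  above); compare conditions imaged with the same optics.
* Equatorial sections only; no 3-D vesicle reconstruction or time-series
  tracking.
* The phase caller assumes a bimodal marker profile; gradual order
  gradients are forced into two classes or a uniform call.
* The simulator's noise model has no detector offset drift or flat-field
  error; the scale-invariance of BE makes gain errors harmless, offset
  errors are not modeled.
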