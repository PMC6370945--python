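# Methods

## Raster conventions

Coordinates are 0-based `(row, col)`; the z index is 0-based from the most
apical slice; all angles are degrees.  Intensities are arbitrary
fluorescence units carried as float64 regardless of on-disk bit depth (the
quantile and fitting arithmetic needs floats, and acquired bit depth is not
fixed by the imaging protocol).  Clone rasters use the fixed dialect
0 = excluded, 1 = wild-type, 2 = mutant.

## Membrane geometry

Cell-label masks are consumed, not computed: segmentation is upstream of
this package.  The membrane skeleton is the set of zero-label pixels with
at least two distinct cell labels in their 3×3 (8-connected) neighbourhood;
the 8-connected rule captures diagonal contacts of one-pixel-wide
skeletons.  Each skeleton pixel carries the set of adjacent cell IDs and a
genotype tag: MUTANT or WILDTYPE only when *all* adjacent cells (genotype
read at the cell centroid) agree, EXCLUDED otherwise.  A clone-border
junction is shared by the two genotypes, so it is counted for neither —
this is an interpretation; assigning border junctions half-weight to each
region would be the main alternative, and the per-wing ratios move by well
under the wing-to-wing spread either way on synthetic wings.

"Around apicolateral junctions" is operationalized as membrane-masked
brightness: each slice is scored by its mean intensity over membrane
pixels, the top k = 3 slices are averaged pixelwise, ties break toward the
apical (smaller z) slice, and the chosen slices need not be consecutive.
This replaces a by-eye slice choice with a deterministic, testable rule.

## Per-cell polarity

For each cell, every adjacent skeleton pixel contributes a boundary sample
`(ψ, I)` where ψ is the axial (mod-180°) direction from the cell centroid
to the pixel.  The polarity statistic is the maximum asymmetry ratio: on a
1° grid of axes θ, R(θ) is the mean intensity of samples within axial
distance 45° of θ divided by the mean of the remaining samples, and

    M = max_θ max(R(θ), 1/R(θ)) ≥ 1,

with the polarity angle the maximizing axis (θ or θ+90 so that the bright
window defines the angle) and ties resolving to the smallest axis.  Axes
where one angular class is empty carry no information and are skipped;
the statistic is degenerate only if no axis splits the samples.  Samples
are unweighted pixel means — whether the historical implementation
weighted by edge length or intensity is unknown, so the simplest rule was
chosen and cross-checked: the intensity-weighted nematic order parameter
m = |Σ I·e^{2iψ}|/Σ I ranks synthetic cells the same way (Spearman ρ > 0.95
in the suite), so conclusions do not hinge on the operationalization.

Cells touching the image border or any EXCLUDED membrane are dropped from
summaries: incomplete or genotype-mixed boundaries bias R(θ).  Cells with
fewer than 8 boundary samples are skipped with a warning.

Angle dispersion uses standard axial statistics: angles are doubled, the
mean resultant length R̄ is computed, and the spread is
½·√(−2 ln R̄) converted to degrees.  R̄ ≈ 0 (e.g. the axial pair
{0°, 90°}) returns NaN and is flagged as maximal dispersion rather than
inventing a number.

On noiseless synthetic wings the wing-level polarity axis (axial mean of
cell angles) recovers the injected axis to within ~1°, and mean magnitude
is strictly increasing in the injected amplitude.  Individual cells
scatter by a few degrees (occasionally >10°) around the injected axis even
without noise: the boundary of a ~14 px hexagon yields ~50 lumpy ψ
samples, and the windowed argmax is sensitive to that rasterization.  This
scatter is a property of the statistic at realistic cell sizes, not of
noise, which is why recovery is asserted at the wing level.

## Synthetic wings

The generator emulates the statistical structure the analysis assumes, not
microscope optics (no PSF beyond Gaussian puncta blobs, no packing
dynamics, no wing curvature).

* **Lattice** — cells are nearest-centre regions of a jittered hexagonal
  point set (integer pitches; distance ties resolve to the
  lexicographically smallest centre, a translation-invariant rule so
  zero-jitter interior cells are congruent), separated by a ~1 px
  zero-label membrane; a breadth-first blob of cells around the field
  centre forms a contiguous mutant clone covering `mutant_fraction` of
  cells (default 0.25).
* **Membrane signal** — a membrane pixel owned (nearest adjacent centroid)
  by cell c has expectation B·s(region)·(1 + a·cos 2(ψ − θ_true))·z_profile[z]
  plus background and Gaussian noise; defaults B = 100, a = 0.3,
  θ_true = 15°, mutant scale s = 0.6, noise SD 5, background 10, and a
  9-slice z-profile peaking at the junctional plane (slices 3–5 brightest).
* **Wing-to-wing variability** — lognormal multiplicative (SD of log 0.15)
  on both overall brightness and the mutant scale, since intensities are
  positive and the per-wing ratio is the unit of analysis.  This puts the
  per-wing ratio SD near 0.10 around the 0.6 median, the scale of spread
  real clone wings show.
* **Puncta** — Poisson counts per genotype region (densities per 1000 px²)
  of isotropic Gaussian blobs with normal radius and peak distributions,
  over background and noise; ground truth returned for testing.
* **Internalization** — per-wing raw intensities at 0/10/30 min with
  per-genotype retention fractions (default 1 / 0.65 / 0.35), lognormal
  wing effects, additive noise and a constant background.
* **FRAP** — 3 pre-bleach frames at 0.5 s, a 1 s bleach to a depth in
  [0.6, 0.75], then 5×5 s + 10×10 s + 26×15 s frames (41 post-bleach
  frames, last at t = 510 s); recovery Y0 + A1(1−e^{−k1 t}) + A2(1−e^{−k2 t})
  with defaults Y0 = 1−depth, A1 = 0.25, k1 = 0.05 s⁻¹, A2 = 0.30,
  k2 = 0.004 s⁻¹ (a fast diffusive phase and a slow trafficking phase that
  does not plateau within the acquisition), multiplied by per-frame
  acquisition bleaching e^{−λ·frame} and offset by a laser-off background;
  the unbleached reference trace carries bleaching and background only.

Passing tests on this generator show the pipeline recovers the parameters
it injects under the stated noise; they do not certify behaviour on real
images with segmentation errors, uneven illumination or non-Gaussian
noise.

## Puncta thresholding

The threshold is calibrated on the wild-type region of the analysis plane:
t\* is the smallest observed intensity v such that the fraction of
wild-type pixels strictly above v is ≤ the target (1% by default).  With
discrete intensities an exact 1% may be unattainable, so ties resolve
downward (achieved ≤ target, and within 1/N below it for continuous
planes).  The same t\* is then applied to the mutant region — the API
takes the threshold as an argument on the mutant path, so recalibration is
impossible by construction.  Puncta are 8-connected components above t\*;
`min_area` defaults to 1 px (both configurable).  Count ratios are
normalized per unit region area because clone and wild-type regions differ
in size; whether the historical analysis did the same is not recorded, but
raw counts would confound region size with density.  The puncta analysis
plane (three sub-junctional slices) is a configuration input, not
auto-detected, since the original choice was by eye.

## FRAP processing and fitting

Preprocessing: subtract the laser-off background from both traces, divide
framewise by the reference's background-subtracted trace rescaled to its
own pre-bleach mean (double normalization; the correction method is a
standard choice, the acquisition protocol does not prescribe one), then
divide by the mean of the trace's own corrected pre-bleach values — which
is therefore exactly 1.  t = 0 sits at the first post-bleach frame; the
bleach interval itself carries no samples.  Frames can be masked (e.g.
focus loss near the end of an acquisition) and masked frames are excluded
from fits.

Fitting: constrained least squares (Y0 ≥ 0, Aᵢ ≥ 0, kᵢ > 0) with
multi-start initialization over a geometric grid of rates spanning
[1/500, 1] s⁻¹ (10 ordered pairs for two-phase); for the two-phase fit the
one-phase optimum with a null slow component is always included as a
start, which guarantees SS₂ ≤ SS₁ and resolves label switching together
with the k1 > k2 reporting convention.  A near-degenerate pair
(|k1 − k2| ≤ 1e−6·k1) falls back to the one-phase fit with a flag.

Model comparison uses the extra-sum-of-squares F test.  Two caveats are
deliberate and documented rather than corrected:

* One- vs two-phase selection tests a null (A2 = 0) on the boundary of the
  constrained parameter space with k2 unidentified under the null, so the
  F test is conservative there (~1–3% rejection at nominal 5% in null
  simulations).  It still almost never prefers the two-phase model on
  one-phase truth, which is the property that matters for model selection.
* The genotype contrast (shared vs genotype-specific parameters for the
  fast (A1,k1), slow (A2,k2) or all components; both exposed because the
  mapping of "first/second phase" to parameters is not formally fixed) is
  an interior null and is calibrated (~5% at nominal 5%) under the iid
  Gaussian errors the test assumes.  Full-pipeline preprocessing induces
  mild within-trace correlation (division by the noisy reference and
  pre-bleach mean), which makes the test slightly conservative on fully
  simulated acquisitions.

## Statistics

scipy.stats provides the kernels: one-sample/paired t (closed form checked
in tests), unpaired t in the equal-variance Student form (the Welch form
is available via a flag; the analysis convention does not specify which),
D'Agostino–Pearson K² as the normality gate — run only at n ≥ 8, below
which it returns "not-assessed" and parametric tests proceed, matching the
practice of using parametric tests when samples are too small to assess —
and one-way ANOVA with Dunnett many-to-one comparisons (the multivariate-t
integration is seeded, so adjusted p-values are reproducible).
Significance stars follow p ≤ 0.05 \*, ≤ 0.01 \*\*, ≤ 0.001 \*\*\*.
Degenerate inputs (zero variance) raise instead of returning NaN.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale: 8×8-cell wings (~115×140 px,
64 cells), 30-wing ratio simulations, 200-trace FRAP recovery batches, and
1000-replicate null calibrations for the t, ANOVA/Dunnett and nested-F
procedures.  These sizes give Monte-Carlo error well inside the asserted
tolerances (±2 SE bands at α = 0.05) while keeping the full suite under a
few minutes.

## Known limitations

No automatic segmentation, no wing-curvature correction, no punctum
tracking or colocalization, no reaction–diffusion FRAP modelling, no
nonparametric fallbacks (the gate has never routed to one), and trichome
polarity scoring is out of scope.  Real trichome/actin channels are not
simulated.
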