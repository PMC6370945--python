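# wingpol

Quantification of planar cell polarity (PCP), endosomal puncta, antibody
internalization kinetics and FRAP recovery in mosaic *Drosophila* pupal
wings.

PCP proteins such as Flamingo (Fmi) and Strabismus localize asymmetrically
at apicolateral cell junctions, and endosomal recycling machinery
(retromer, Snx27) maintains their junctional levels.  Experiments that
probe this biology image wings carrying marked mutant clones and ask, wing
by wing: how much junctional protein is present in mutant versus wild-type
tissue, how strongly and in which direction each cell is polarized, how
much labeled protein moves into intracellular puncta over a chase, and how
fast bleached junctional protein recovers.  `wingpol` implements that
entire quantification chain as a tested, reusable library with a synthetic
data generator standing in for raw microscopy.

## What it computes

* **Bright-slice projection** — the three z-slices with highest mean
  membrane intensity are selected and averaged into the analysis plane.
* **Per-cell polarity** — the *maximum asymmetry ratio*: for each candidate
  axis θ on a 1° grid, R(θ) compares mean boundary intensity inside a 90°
  axial window against the complement; the magnitude is
  M = max<sub>θ</sub> max(R, 1/R) ≥ 1 and the polarity angle is the
  maximizing axis (mod 180°).  Wing summaries report the mean M and the
  axial circular spread ½√(−2 ln R̄) of cell angles (computed on doubled
  angles).
* **Clone intensity ratios** — mean membrane intensity in mutant vs
  wild-type regions of the same wing (clone-border junctions excluded),
  tested against 1.0 with one-sample t tests; paired t tests compare
  regions within wings.
* **Internalization time courses** — total extracellular signal per region
  at 0/10/30 min chase, laser-off background subtracted, normalized to the
  genotype's 0-min mean; one-way ANOVA with Dunnett's many-to-one
  comparisons against 0 min.
* **Puncta** — an intensity threshold calibrated so that at most 1% of
  wild-type area is above it, then applied unchanged to mutant tissue;
  puncta are 8-connected components with per-punctum area, integrated and
  mean intensity; per-wing mutant/wild-type ratios of count density, size
  and intensity are tested against 1.0.
* **FRAP** — traces are background-subtracted, corrected for acquisition
  bleaching against an unbleached reference, and normalized to their
  pre-bleach mean; recovery is fitted as
  I(t) = Y0 + Σᵢ Aᵢ(1 − e^(−kᵢt)) for one or two phases under
  constraints (Aᵢ ≥ 0, k1 > k2 > 0) with multi-start least squares, and
  nested fits are compared with the extra-sum-of-squares F test
  F = ((SS₁−SS₂)/(p₂−p₁)) / (SS₂/(n−p₂)).

## Worked example

Simulate one mosaic wing (8×8 jittered hexagonal cells, mutant clone at
60% membrane intensity, 30% polarity amplitude along a 15° axis) and run
the polarity pipeline:

```python
from wingpol import synthwing as sw, junctions as jx, polarity as pol
from wingpol.imgio import Region

spec = sw.WingSpec(seed=42)
label, clone = sw.make_lattice(spec)
stack = sw.render_membrane_stack(label, clone, spec)
skel = jx.build_skeleton(label, clone)
plane, chosen = jx.select_bright_slices(stack, skel)   # chosen == [3, 4, 5]

cells = pol.quantify_wing(plane, label, skel)
wt = pol.wing_summary(cells, Region.WILDTYPE)
print(wt.n_cells, round(wt.mean_magnitude, 3), round(wt.angle_spread, 1))
# 14 1.348 5.7
mw = pol.region_membrane_mean(plane, skel, Region.WILDTYPE) - spec.background
mm = pol.region_membrane_mean(plane, skel, Region.MUTANT) - spec.background
print(round(mm / mw, 3))
# 0.649
```

The 14 scorable wild-type cells have mean polarity magnitude 1.348 (their
brightest 90° window is ~35% brighter than the rest of the boundary) with
only 5.7° spread in polarity angle — a coordinately polarized wing — and
the mutant clone retains 65% of wild-type junctional signal this wing
(the injected median is 60%, with lognormal wing-to-wing variability).
Across 8 simulated wings the one-sample t test of the ratios against 1.0
gives t = −10.89, df = 7, p = 1.2e−05 (\*\*\*).

The same stages are scriptable from the shell:

```sh
wingpol simulate --kind wing --seed 42 --out sim/
wingpol polarity --stack sim/stack.tif --labels sim/labels.tif \
    --clones sim/clones.tif --out results/
```

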