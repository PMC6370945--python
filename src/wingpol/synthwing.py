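"""Synthetic wings, puncta fields, internalization series and FRAP traces.

Every generator is deterministic given its seed and returns ground truth
alongside the data, so each analysis stage can be tested by parameter
recovery.  The generators emulate the statistical structure the analysis
assumes — a polarized junctional signal on an epithelial lattice, clonal
regions with scaled intensity, Poisson puncta fields, lognormal wing-to-wing
variability, and two-phase FRAP recovery with acquisition bleaching — not
the optics of a microscope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SpecError
from .frap import FrapProtocol, recovery_model
from .imgio import CloneMap, ImageStack, LabelMask, Region
from .internalization import CHASE_TIMES_MIN, TimecourseRecord
from .junctions import axial_angle_deg

__all__ = [
    "WingSpec",
    "PunctaSpec",
    "FrapSimSpec",
    "make_lattice",
    "render_membrane_stack",
    "render_puncta_plane",
    "simulate_internalization",
    "simulate_frap_trace",
]


@dataclass
class WingSpec:
    """Geometry and signal model of a synthetic mosaic wing.

    The defaults approximate the study's imaging regime: hexagonally packed
    cells ~15 px across, a mutant clone covering about a quarter of the
    field, 30% polarity amplitude along a single tissue axis, and nine
    z-slices whose brightness peaks at the apicolateral junctions.
    """

    n_cell_rows: int = 8
    n_cell_cols: int = 8
    cell_diameter_px: float = 14.0
    jitter: float = 0.15                  # fraction of cell diameter
    base_membrane_intensity: float = 100.0
    polarity_amplitude: float = 0.3       # a in [0, 1)
    polarity_axis_deg: float = 15.0       # true axis θ in [0, 180)
    region_scale_mutant: float = 0.6      # mutant membrane multiplier
    wing_scale_sd_log: float = 0.15       # lognormal wing-to-wing variability (sd of log)
    noise_sd: float = 5.0
    background: float = 10.0
    z_profile: tuple[float, ...] = (0.3, 0.5, 0.75, 0.95, 1.0, 0.9, 0.7, 0.5, 0.3)
    mutant_fraction: float = 0.25         # fraction of cells in the clone
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_diameter_px < 3:
            raise SpecError("cell_diameter_px must be >= 3")
        if not (0 <= self.polarity_amplitude < 1):
            raise SpecError("polarity_amplitude must be in [0, 1)")
        if not (0 <= self.polarity_axis_deg < 180):
            raise SpecError("polarity_axis_deg must be in [0, 180)")
        if self.region_scale_mutant <= 0 or self.base_membrane_intensity <= 0:
            raise SpecError("intensity scales must be positive")
        if self.jitter < 0 or self.noise_sd < 0 or not (0 <= self.mutant_fraction <= 1):
            raise SpecError("jitter/noise/mutant_fraction out of range")
        if self.wing_scale_sd_log < 0:
            raise SpecError("wing_scale_sd_log must be >= 0")


@dataclass
class PunctaSpec:
    """Sub-junctional puncta field: Poisson counts of Gaussian blobs."""

    density_wt_per_kpx: float = 2.0       # puncta per 1000 px²
    density_mut_per_kpx: float = 2.0
    radius_mean_px: float = 2.0
    radius_sd_px: float = 0.4
    peak_mean: float = 80.0
    peak_sd: float = 10.0
    background: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_wt_per_kpx < 0 or self.density_mut_per_kpx < 0:
            raise SpecError("densities must be >= 0")
        if self.radius_mean_px <= 0:
            raise SpecError("radius mean must be > 0")


@dataclass
class FrapSimSpec:
    """Two-phase exponential FRAP recovery with acquisition bleaching.

    The default kinetics follow the fitted regime of the study's traces: a
    fast diffusive phase (seconds–tens of seconds) and a slow trafficking
    phase that has not plateaued by 510 s, with 60–75% bleach depth.
    """

    amp_fast: float = 0.25                # A1
    amp_slow: float = 0.30                # A2
    rate_fast: float = 0.05               # k1, s^-1
    rate_slow: float = 0.004              # k2, s^-1
    bleach_depth: float = 0.675           # fraction bleached, in [0.6, 0.75]
    y0: float | None = None               # post-bleach floor; default 1 - bleach_depth
    acquisition_bleach_rate: float = 0.002  # per frame
    background: float = 20.0
    prebleach_level: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.y0 is None:
            self.y0 = 1.0 - self.bleach_depth
        if self.y0 < 0 or self.amp_fast < 0 or self.amp_slow < 0:
            raise SpecError("Y0 and amplitudes must be >= 0")
        if self.amp_fast > 0 and self.amp_slow > 0 and not self.rate_fast > self.rate_slow:
            raise SpecError("rates must satisfy k1 > k2")
        if self.rate_fast <= 0 or self.rate_slow <= 0:
            raise SpecError("rates must be positive")
        if self.y0 + self.amp_fast + self.amp_slow > 1.0 + 1e-12:
            raise SpecError("recovery cannot exceed the prebleach level (Y0 + A1 + A2 <= 1)")
        if self.acquisition_bleach_rate < 0 or self.noise_sd < 0:
            raise SpecError("bleach rate and noise must be >= 0")


# ---------------------------------------------------------------------------
# epithelium lattice

def _hex_centers(spec: WingSpec, rng: np.random.Generator) -> np.ndarray:
    d = spec.cell_diameter_px
    row_pitch = max(int(round(d * np.sqrt(3) / 2)), 2)
    col_pitch = max(int(round(d)), 2)
    centers = []
    for i in range(spec.n_cell_rows):
        for j in range(spec.n_cell_cols):
            r = (i + 1) * row_pitch
            c = (j + 1) * col_pitch + (col_pitch // 2 if i % 2 else 0)
            centers.append((r, c))
    centers = np.array(centers, dtype=np.float64)
    if spec.jitter > 0:
        centers += rng.uniform(-spec.jitter * d, spec.jitter * d, size=centers.shape)
    return centers


def make_lattice(spec: WingSpec) -> tuple[LabelMask, CloneMap]:
    """Jittered hexagonal cell lattice with a contiguous mutant clone.

    Cells are nearest-center (Voronoi) regions of the jittered hex point
    set, separated by a ~1-px zero-label membrane; a breadth-first blob of
    cells around the field center is assigned MUTANT until it covers
    ``mutant_fraction`` of all cells.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _hex_centers(spec, rng)
    d = spec.cell_diameter_px
    row_pitch = max(int(round(d * np.sqrt(3) / 2)), 2)
    col_pitch = max(int(round(d)), 2)
    h = (spec.n_cell_rows + 1) * row_pitch + row_pitch // 2
    w = (spec.n_cell_cols + 1) * col_pitch + col_pitch

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    # nearest-centre assignment; distance ties go to the lexicographically
    # smallest (row, col) centre — a translation-invariant rule, so congruent
    # cells rasterize to congruent (equal-area) pixel sets at zero jitter
    lex = np.lexsort((centers[:, 1], centers[:, 0]))
    centers_sorted = centers[lex]
    d2, neigh = cKDTree(centers_sorted).query(pts, k=min(6, centers.shape[0]))
    d2 = np.atleast_2d(d2.T).T
    neigh = np.atleast_2d(neigh.T).T
    tied = d2 <= d2[:, :1] + 1e-9
    owner_sorted = np.where(tied, neigh, centers.shape[0]).min(axis=1)
    full = (lex[owner_sorted] + 1).reshape(h, w).astype(np.int64)

    # carve a thin membrane: a pixel whose right or lower neighbour belongs
    # to a different cell becomes membrane (one side of each boundary)
    memb = np.zeros((h, w), dtype=bool)
    memb[:, :-1] |= full[:, :-1] != full[:, 1:]
    memb[:-1, :] |= full[:-1, :] != full[1:, :]
    labels = full.copy()
    labels[memb] = 0

    # contiguous mutant blob grown from the cell nearest the field centre
    n_cells = centers.shape[0]
    n_mut = int(round(spec.mutant_fraction * n_cells))
    mutant: set[int] = set()
    if n_mut > 0:
        centre = np.array([h / 2, w / 2])
        order = np.argsort(np.linalg.norm(centers - centre, axis=1))
        tree = cKDTree(centers)
        start = int(order[0])
        frontier = [start]
        while frontier and len(mutant) < n_mut:
            cur = frontier.pop(0)
            if cur in mutant:
                continue
            mutant.add(cur)
            dist, neigh = tree.query(centers[cur], k=min(8, n_cells))
            for nb in np.atleast_1d(neigh):
                if int(nb) not in mutant:
                    frontier.append(int(nb))

    regions = np.full((h, w), int(Region.WILDTYPE), dtype=np.int8)
    mut_mask = np.isin(full - 1, sorted(mutant))
    regions[mut_mask] = int(Region.MUTANT)
    return LabelMask(labels), CloneMap(regions)


def render_membrane_stack(label: LabelMask, clone: CloneMap, spec: WingSpec) -> ImageStack:
    """Render a polarized junctional signal onto the lattice membrane.

    A membrane pixel belonging (by nearest adjacent centroid) to cell c gets
    expectation  B · s(region) · (1 + a·cos 2(ψ − θ)) · z_profile[z]  with ψ
    the centroid→pixel axial direction, plus background and Gaussian noise;
    non-membrane pixels carry background and noise only.  Negative draws are
    clipped at zero.

    Wing-to-wing biological variability is lognormal multiplicative
    (``wing_scale_sd_log``): one factor on the overall brightness B and an
    independent one on the mutant scale s, so per-wing mutant/wild-type
    ratios scatter around ``region_scale_mutant`` the way real clone wings
    scatter around their typical ratio.
    """
    from .junctions import build_skeleton  # local import to avoid cycle at import time

    rng = np.random.default_rng(spec.seed + 1)
    if spec.wing_scale_sd_log > 0:
        overall = float(np.exp(rng.normal(0.0, spec.wing_scale_sd_log)))
        mut_factor = float(np.exp(rng.normal(0.0, spec.wing_scale_sd_log)))
    else:
        overall = mut_factor = 1.0
    spec = dataclasses.replace(
        spec,
        base_membrane_intensity=spec.base_membrane_intensity * overall,
        region_scale_mutant=spec.region_scale_mutant * mut_factor,
    )
    skel = build_skeleton(label, clone)
    h, w = label.shape
    nz = len(spec.z_profile)

    # per-pixel owning cell = adjacent cell with nearest centroid
    psis = np.empty(skel.n_pixels)
    scales = np.empty(skel.n_pixels)
    for i, (px, adj) in enumerate(zip(skel.pixels, skel.adjacency)):
        cands = sorted(adj)
        cents = np.array([skel.cell_centroids[c] for c in cands])
        dvec = px - cents
        owner = int(np.argmin((dvec ** 2).sum(axis=1)))
        psis[i] = axial_angle_deg(dvec[owner, 0], dvec[owner, 1])
        own_regions = [skel.cell_region[c] for c in cands]
        sc = [spec.region_scale_mutant if r == int(Region.MUTANT) else 1.0
              for r in own_regions]
        scales[i] = float(np.mean(sc))  # clone-border pixels: mean of the two scales

    angular = 1.0 + spec.polarity_amplitude * np.cos(
        2.0 * np.radians(psis - spec.polarity_axis_deg))
    base = spec.base_membrane_intensity * scales * angular

    voxels = np.full((nz, h, w), spec.background, dtype=np.float64)
    r_idx, c_idx = skel.pixels[:, 0], skel.pixels[:, 1]
    for z, zmul in enumerate(spec.z_profile):
        voxels[z, r_idx, c_idx] += base * zmul
    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, size=voxels.shape)
    np.clip(voxels, 0.0, None, out=voxels)
    return ImageStack(voxels, channel_name="synthetic-membrane")


# ---------------------------------------------------------------------------
# puncta field

def render_puncta_plane(
    label: LabelMask, clone: CloneMap, spec: PunctaSpec,
) -> tuple[ImageStack, pd.DataFrame]:
    """Poisson puncta per genotype region as isotropic Gaussian blobs.

    Returns a single-plane stack and the ground-truth punctum table
    (region, row, col, radius, peak).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = clone.shape
    plane = np.full((h, w), spec.background, dtype=np.float64)
    truth_rows = []
    for region, density in ((Region.WILDTYPE, spec.density_wt_per_kpx),
                            (Region.MUTANT, spec.density_mut_per_kpx)):
        mask = clone.mask(region)
        area = int(mask.sum())
        if area == 0 or density == 0:
            continue
        count = rng.poisson(density * area / 1000.0)
        if count == 0:
            continue
        rows, cols = np.nonzero(mask)
        pick = rng.integers(0, rows.size, size=count)
        radii = np.clip(rng.normal(spec.radius_mean_px, spec.radius_sd_px, count),
                        0.5, None)
        peaks = np.clip(rng.normal(spec.peak_mean, spec.peak_sd, count), 1.0, None)
        for r0, c0, rad, pk in zip(rows[pick], cols[pick], radii, peaks):
            ext = int(np.ceil(3 * rad))
            r_lo, r_hi = max(r0 - ext, 0), min(r0 + ext + 1, h)
            c_lo, c_hi = max(c0 - ext, 0), min(c0 + ext + 1, w)
            rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                                 indexing="ij")
            plane[r_lo:r_hi, c_lo:c_hi] += pk * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * rad ** 2))
            truth_rows.append({"region": region.name, "row": int(r0), "col": int(c0),
                               "radius_px": float(rad), "peak": float(pk)})
    if spec.noise_sd > 0:
        plane += rng.normal(0.0, spec.noise_sd, size=plane.shape)
    np.clip(plane, 0.0, None, out=plane)
    truth = pd.DataFrame(truth_rows, columns=["region", "row", "col", "radius_px", "peak"])
    return ImageStack(plane[None], channel_name="synthetic-puncta"), truth


# ---------------------------------------------------------------------------
# internalization time series

def simulate_internalization(
    n_wings: int = 6,
    genotypes: tuple[str, ...] = ("WILDTYPE", "MUTANT"),
    retention: dict[str, dict[int, float]] | None = None,
    base_intensity: float = 1000.0,
    background: float = 50.0,
    wing_effect_sd: float = 0.15,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> tuple[list[TimecourseRecord], float]:
    """Raw extracellular intensities at chase times {0, 10, 30} min.

    Each wing×timepoint draws an independent multiplicative lognormal wing
    effect (σ of log = ``wing_effect_sd``) and additive Gaussian noise on
    top of ``base_intensity × retention[genotype][time] + background``.
    Default retention halves roughly every 15 min, matching an extracellular
    pool that decays by internalization over the 30-min chase.

    Returns the raw records and the background value to feed to
    :func:`wingpol.internalization.normalize_timecourse`.
    """
    if retention is None:
        retention = {g: {0: 1.0, 10: 0.65, 30: 0.35} for g in genotypes}
    rng = np.random.default_rng(seed)
    records: list[TimecourseRecord] = []
    for gt in genotypes:
        for t in CHASE_TIMES_MIN:
            for i in range(n_wings):
                effect = float(np.exp(rng.normal(0.0, wing_effect_sd))) if wing_effect_sd else 1.0
                raw = base_intensity * retention[gt][t] * effect + background
                raw += rng.normal(0.0, noise_sd) if noise_sd else 0.0
                records.append(TimecourseRecord(f"{gt}-w{i}-t{t}", gt, t, float(raw)))
    return records, background


# ---------------------------------------------------------------------------
# FRAP traces

def simulate_frap_trace(
    spec: FrapSimSpec, protocol: FrapProtocol = FrapProtocol(),
) -> tuple[np.ndarray, np.ndarray, float]:
    """One FRAP acquisition: (raw trace, unbleached reference trace, background).

    Prebleach frames sit at ``prebleach_level``; the first post-bleach frame
    starts at Y0 = 1 − bleach_depth and recovers per the two-phase
    association model.  Both traces are multiplied by
    exp(−λ·frame_index) acquisition bleaching and offset by the laser-off
    background; Gaussian noise is added to each.
    """
    rng = np.random.default_rng(spec.seed)
    npre = protocol.n_prebleach
    t_post = protocol.post_times_s()
    model = recovery_model(t_post, spec.y0, (spec.amp_fast, spec.amp_slow),
                           (spec.rate_fast, spec.rate_slow))
    signal = np.concatenate([np.full(npre, spec.prebleach_level), model])
    frames = np.arange(signal.size)
    decay = np.exp(-spec.acquisition_bleach_rate * frames)
    raw = signal * decay + spec.background
    reference = spec.prebleach_level * decay + spec.background
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, raw.size)
        reference = reference + rng.normal(0.0, spec.noise_sd, reference.size)
    return raw, reference, spec.background
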