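"""Per-cell planar-polarity statistics and clone intensity-ratio tests.

The per-cell polarity statistic is the *maximum asymmetry ratio*: for every
candidate axis θ on a 1° grid, boundary samples are split into an axial
window (|psi − θ| ≤ 45° mod 180) and its complement, and R(θ) is the ratio
of the window's mean intensity to the complement's.  The polarity magnitude
M is max over θ of max(R, 1/R) ≥ 1 and the polarity angle is the axis
achieving it (mod 180°).  An intensity-weighted nematic order parameter is
provided as an independent cross-check of the same biology.

Angle dispersion uses standard axial statistics: angles are doubled, the
mean resultant length R̄ of the unit vectors is computed, and the circular
standard deviation sqrt(−2 ln R̄) is halved and converted back to degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as wstats
from .errors import DegenerateDataError, GeometryError, InsufficientSamplesError, SpecError
from .imgio import LabelMask, Region
from .junctions import BoundarySample, MembraneSkeleton, sample_cell_boundary

__all__ = [
    "CellPolarity",
    "WingPolaritySummary",
    "RatioRecord",
    "cell_polarity",
    "nematic_order",
    "axial_spread",
    "wing_summary",
    "region_membrane_mean",
    "clone_ratio_test",
    "paired_region_test",
    "quantify_wing",
]

MIN_BOUNDARY_SAMPLES = 8


@dataclass
class CellPolarity:
    """Polarity readout for one cell."""

    cell_id: int
    magnitude: float       # max asymmetry ratio, dimensionless >= 1
    angle: float           # axis of maximal asymmetry, degrees in [0, 180)
    mean_boundary_intensity: float
    region: int = int(Region.WILDTYPE)
    n_samples: int = 0


@dataclass
class WingPolaritySummary:
    region: int
    n_cells: int
    mean_magnitude: float
    angle_spread: float     # degrees; NaN when resultant length is ~0
    spread_defined: bool = True


@dataclass
class RatioRecord:
    wing_id: str
    measure: str
    ratio: float            # mutant mean / wild-type mean, > 0


def _sample_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        psi = np.asarray(samples[0], dtype=np.float64)
        inten = np.asarray(samples[1], dtype=np.float64)
    else:
        psi = np.array([s.psi for s in samples], dtype=np.float64)
        inten = np.array([s.intensity for s in samples], dtype=np.float64)
    return psi % 180.0, inten


def cell_polarity(
    samples: list[BoundarySample] | tuple[np.ndarray, np.ndarray],
    axis_step: float = 1.0,
    half_width: float = 45.0,
    cell_id: int | None = None,
    region: int = int(Region.WILDTYPE),
) -> CellPolarity:
    """Maximum asymmetry ratio of boundary intensity over a grid of axes.

    For each axis θ in {0, axis_step, ..., 180 − axis_step} the asymmetry
    ratio R(θ) compares mean intensity inside the axial window of half-width
    ``half_width`` with the mean over the remaining samples.  Returns
    M = max_θ max(R, 1/R) and the corresponding axis (θ when R ≥ 1/R, else
    θ + 90 mod 180).  Ties resolve to the smallest axis.
    """
    psi, inten = _sample_arrays(samples)
    n = psi.size
    if n < MIN_BOUNDARY_SAMPLES:
        raise InsufficientSamplesError(
            f"cell polarity needs >= {MIN_BOUNDARY_SAMPLES} samples, got {n}")
    if axis_step <= 0 or not (0 < half_width < 90):
        raise SpecError("axis_step must be > 0 and half_width in (0, 90)")

    axes = np.arange(0.0, 180.0, axis_step)
    delta = np.abs(psi[None, :] - axes[:, None]) % 180.0
    dist = np.minimum(delta, 180.0 - delta)          # axial distance in [0, 90]
    in_window = dist <= half_width
    n_in = in_window.sum(axis=1)
    # axes where either angular class is empty carry no asymmetry information
    # (samples may cluster on few axes); they are skipped, and the statistic
    # is degenerate only when no axis has both classes populated
    valid = (n_in > 0) & (n_in < n)
    if not valid.any():
        raise DegenerateDataError(
            "degenerate boundary geometry: no axis has both angular classes populated")
    sum_in = inten @ in_window.T
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_in = sum_in / n_in
        mean_out = (inten.sum() - sum_in) / (n - n_in)
    if np.any(mean_out[valid] == 0) or np.any(mean_in[valid] == 0):
        raise DegenerateDataError("zero mean intensity in an angular class")
    ratio = np.where(valid, mean_in / mean_out, 1.0)
    m_axis = np.where(valid, np.maximum(ratio, 1.0 / ratio), -np.inf)
    best = int(np.argmax(m_axis))                    # first max -> smallest axis
    angle = axes[best] if ratio[best] >= 1.0 / ratio[best] else (axes[best] + 90.0) % 180.0
    return CellPolarity(
        cell_id=cell_id if cell_id is not None else -1,
        magnitude=float(m_axis[best]),
        angle=float(angle),
        mean_boundary_intensity=float(inten.mean()),
        region=region,
        n_samples=n,
    )


def nematic_order(samples) -> tuple[float, float]:
    """Intensity-weighted nematic order parameter and axis.

    m = |Σ I·e^{2i·psi}| / Σ I with the axis at half the resultant's phase.
    Used as an independent operationalization to cross-check the
    asymmetry-ratio ranking.
    """
    psi, inten = _sample_arrays(samples)
    if inten.sum() <= 0:
        raise DegenerateDataError("nematic order undefined for zero total intensity")
    z = np.sum(inten * np.exp(2j * np.radians(psi))) / inten.sum()
    return float(np.abs(z)), float((np.degrees(np.angle(z)) / 2.0) % 180.0)


def axial_spread(angles_deg) -> float:
    """Circular standard deviation of axial (mod 180°) angles, in degrees.

    Angles are doubled onto the circle; with mean resultant length R̄ the
    spread is (1/2)·sqrt(−2 ln R̄) converted to degrees.  Returns NaN when
    R̄ ≈ 0 (antipodal axial data: dispersion is maximal and the statistic is
    undefined).
    """
    arr = np.asarray(angles_deg, dtype=np.float64).ravel()
    if arr.size == 0:
        raise SpecError("axial_spread needs at least one angle")
    z = np.mean(np.exp(2j * np.radians(arr)))
    rbar = float(np.abs(z))
    if rbar < 1e-12:
        return float("nan")
    rbar = min(rbar, 1.0)
    return float(np.degrees(0.5 * np.sqrt(-2.0 * np.log(rbar))))


def wing_summary(cells: list[CellPolarity], region: int | Region) -> WingPolaritySummary:
    """Per-wing mean polarity magnitude and axial angle spread for a region."""
    region = int(region)
    sel = [c for c in cells if c.region == region]
    if not sel:
        raise SpecError(f"no cells in region {region}")
    mags = np.array([c.magnitude for c in sel])
    angles = [c.angle for c in sel]
    spread = axial_spread(angles) if len(angles) >= 2 else float("nan")
    return WingPolaritySummary(
        region=region,
        n_cells=len(sel),
        mean_magnitude=float(mags.mean()),
        angle_spread=spread,
        spread_defined=bool(np.isfinite(spread)),
    )


def region_membrane_mean(plane: np.ndarray, skeleton: MembraneSkeleton,
                         region: int | Region) -> float:
    """Arithmetic mean of plane intensity over skeleton pixels of a region."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.shape != skeleton.shape:
        raise GeometryError(f"plane shape {plane.shape} != skeleton shape {skeleton.shape}")
    sel = skeleton.region == int(region)
    if not sel.any():
        raise GeometryError(f"no membrane pixels tagged region {int(region)}")
    px = skeleton.pixels[sel]
    return float(plane[px[:, 0], px[:, 1]].mean())


def clone_ratio_test(ratios: list[RatioRecord] | np.ndarray) -> wstats.TestResult:
    """One-sample t test of per-wing mutant/wild-type ratios against 1.0."""
    if len(ratios) and isinstance(ratios[0], RatioRecord):
        values = np.array([r.ratio for r in ratios], dtype=np.float64)
    else:
        values = np.asarray(ratios, dtype=np.float64)
    if values.size < 2:
        raise SpecError("clone ratio test needs >= 2 wings")
    if np.any(values <= 0):
        raise SpecError("ratios must be positive")
    return wstats.one_sample_t(values, 1.0)


def paired_region_test(pairs) -> wstats.TestResult:
    """Paired t test of per-wing (wild-type, mutant) value pairs."""
    return wstats.paired_t(pairs)


# ---------------------------------------------------------------------------
# wing-level pipeline

def _border_cells(label: LabelMask) -> set[int]:
    lab = label.labels
    edge = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    return set(int(i) for i in np.unique(edge) if i > 0)


def quantify_wing(
    plane: np.ndarray,
    label: LabelMask,
    skeleton: MembraneSkeleton,
    axis_step: float = 1.0,
    half_width: float = 45.0,
) -> list[CellPolarity]:
    """Per-cell polarity for every scorable cell of a wing.

    Cells touching the image border or the EXCLUDED region are dropped
    (incomplete or genotype-mixed boundaries bias the asymmetry ratio): a
    cell is excluded if its centroid lies in EXCLUDED territory or any of
    its boundary pixels is a clone-border membrane.  Cells with too few
    boundary samples are skipped with a warning.
    """
    border = _border_cells(label)
    out: list[CellPolarity] = []
    excluded_code = int(Region.EXCLUDED)
    for cid in label.cell_ids:
        cid = int(cid)
        if cid in border:
            continue
        region = skeleton.cell_region.get(cid, excluded_code)
        if region == excluded_code:
            continue
        idx = skeleton.pixel_indices_for_cell(cid)
        if idx.size and np.any(skeleton.region[idx] == excluded_code):
            continue
        try:
            samples = sample_cell_boundary(plane, label, cid, skeleton=skeleton)
            cp = cell_polarity(samples, axis_step=axis_step, half_width=half_width,
                               cell_id=cid, region=region)
        except InsufficientSamplesError:
            warnings.warn(f"cell {cid}: too few boundary samples; skipped", stacklevel=2)
            continue
        out.append(cp)
    return out


def cells_to_frame(cells: list[CellPolarity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "region": [Region(c.region).name for c in cells],
            "magnitude": [c.magnitude for c in cells],
            "angle_deg": [c.angle for c in cells],
            "mean_boundary_intensity": [c.mean_boundary_intensity for c in cells],
            "n_samples": [c.n_samples for c in cells],
        }
    )
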