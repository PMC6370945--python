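"""Antibody-internalization quantification: extracellular-label time courses
and area-fraction-calibrated intracellular puncta.

The time course measures total extracellular signal per genotype region of
each wing at chase times 0/10/30 min, subtracts laser-off background, and
normalizes each genotype to its mean 0-min value.

Puncta detection calibrates an intensity threshold on the wild-type region
so that (at most) a target fraction — 1% by default — of wild-type area lies
strictly above it; the *same* threshold is then applied to the mutant region
of the same wing.  Puncta are 8-connected components above threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as wstats
from .errors import GeometryError, ProtocolError, SpecError
from .imgio import Region
from .junctions import MembraneSkeleton

__all__ = [
    "TimecourseRecord",
    "PunctaSet",
    "CHASE_TIMES_MIN",
    "extracellular_timecourse",
    "normalize_timecourse",
    "timecourse_anova",
    "find_puncta_threshold",
    "extract_puncta",
    "puncta_ratio_tests",
]

#: chase timepoints of the internalization protocol, minutes after wash-off
CHASE_TIMES_MIN = (0, 10, 30)

_PUNCTA_CONNECTIVITY = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class TimecourseRecord:
    wing_id: str
    genotype_region: str
    time_min: int
    raw_intensity: float
    normalized_intensity: float = float("nan")


@dataclass
class PunctaSet:
    """Above-threshold connected components in one genotype region."""

    threshold: float
    achieved_fraction: float
    region: str
    region_area_px: int
    puncta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def count(self) -> int:
        return len(self.puncta)

    @property
    def density_per_kpx(self) -> float:
        """Puncta per 1000 px² of region area."""
        return 1000.0 * self.count / self.region_area_px

    def mean_of(self, column: str) -> float:
        return float(self.puncta[column].mean()) if self.count else float("nan")


# ---------------------------------------------------------------------------
# extracellular time course

def normalize_timecourse(records: list[TimecourseRecord],
                         background_per_record: dict | float = 0.0) -> list[TimecourseRecord]:
    """Background-subtract and normalize raw intensities per genotype.

    Background may be a scalar (already scaled to the record's region, e.g.
    background-per-pixel × pixel count) or a dict keyed by
    ``(wing_id, genotype_region, time_min)``.  Each genotype's records are
    divided by the mean background-subtracted 0-min value of that genotype,
    so the 0-min group mean is exactly 1.0 by construction.
    """
    def bg_for(rec: TimecourseRecord) -> float:
        if isinstance(background_per_record, dict):
            return float(background_per_record[(rec.wing_id, rec.genotype_region, rec.time_min)])
        return float(background_per_record)

    corrected: dict[int, float] = {}
    for i, rec in enumerate(records):
        val = rec.raw_intensity - bg_for(rec)
        if val < 0:
            warnings.warn(
                f"wing {rec.wing_id} t={rec.time_min}: background exceeds signal; clipped to 0",
                stacklevel=2)
            val = 0.0
        corrected[i] = val

    genotypes = sorted({r.genotype_region for r in records})
    out: list[TimecourseRecord] = []
    for gt in genotypes:
        idx = [i for i, r in enumerate(records) if r.genotype_region == gt]
        zero = [corrected[i] for i in idx if records[i].time_min == 0]
        if not zero:
            raise ProtocolError(f"genotype {gt}: no 0-min reference measurement")
        ref = float(np.mean(zero))
        if ref <= 0:
            warnings.warn(f"genotype {gt}: zero 0-min reference; normalized values are 0",
                          stacklevel=2)
        for i in idx:
            r = records[i]
            norm = corrected[i] / ref if ref > 0 else 0.0
            out.append(TimecourseRecord(r.wing_id, r.genotype_region, r.time_min,
                                        r.raw_intensity, norm))
    return out


def extracellular_timecourse(
    planes: dict[tuple[str, int], np.ndarray],
    skeletons: dict[str, MembraneSkeleton],
    laser_off_background: float,
    regions: tuple[Region, ...] = (Region.WILDTYPE, Region.MUTANT),
) -> list[TimecourseRecord]:
    """Quantify total extracellular signal per region over the chase series.

    ``planes`` maps ``(wing_id, time_min)`` to the bright-slice-averaged
    plane of that acquisition; ``skeletons`` gives each wing's region-tagged
    membrane.  Total (summed) signal over the region's membrane pixels has
    ``laser_off_background`` × pixel-count subtracted before per-genotype
    normalization to the 0-min mean.
    """
    records: list[TimecourseRecord] = []
    backgrounds: dict[tuple[str, str, int], float] = {}
    for (wing_id, t), plane in planes.items():
        if wing_id not in skeletons:
            raise GeometryError(f"no skeleton for wing {wing_id}")
        skel = skeletons[wing_id]
        plane = np.asarray(plane, dtype=np.float64)
        if plane.shape != skel.shape:
            raise GeometryError(f"plane/skeleton shape mismatch for wing {wing_id}")
        for region in regions:
            sel = skel.region == int(region)
            if not sel.any():
                continue
            px = skel.pixels[sel]
            total = float(plane[px[:, 0], px[:, 1]].sum())
            key = (wing_id, Region(region).name, int(t))
            backgrounds[key] = laser_off_background * int(sel.sum())
            records.append(TimecourseRecord(wing_id, Region(region).name, int(t), total))
    if not records:
        raise ProtocolError("no measurable regions in any wing")
    return normalize_timecourse(records, backgrounds)


def timecourse_anova(records: list[TimecourseRecord], control_time: int = 0,
                     rng=0) -> dict[str, tuple[wstats.TestResult, list[wstats.TestResult]]]:
    """Per-genotype one-way ANOVA over chase times with Dunnett vs 0 min."""
    out = {}
    for gt in sorted({r.genotype_region for r in records}):
        recs = [r for r in records if r.genotype_region == gt]
        times = sorted({r.time_min for r in recs})
        if control_time not in times:
            raise ProtocolError(f"genotype {gt}: control time {control_time} missing")
        groups = [[r.normalized_intensity for r in recs if r.time_min == t] for t in times]
        anova, dunnett = wstats.anova_dunnett(
            groups, control_index=times.index(control_time), rng=rng)
        noncontrol = [t for t in times if t != control_time]
        for t, res in zip(noncontrol, dunnett):
            res.test_name = f"Dunnett {t} min vs {control_time} min"
        out[gt] = (anova, dunnett)
    return out


# ---------------------------------------------------------------------------
# puncta

def find_puncta_threshold(plane: np.ndarray, wt_region_mask: np.ndarray,
                          target_fraction: float = 0.01) -> tuple[float, float]:
    """Calibrate the puncta threshold on the wild-type region.

    Returns ``(threshold, achieved_fraction)`` where the threshold is the
    smallest value ``v`` such that the fraction of wild-type pixels with
    intensity strictly above ``v`` is at most ``target_fraction`` (so the
    achieved fraction never exceeds the target; with continuous-valued
    planes it lies within 1/N below it).  ``target_fraction = 1`` places the
    threshold below the region minimum so every pixel is puncta.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise SpecError(f"target_fraction must be in (0, 1], got {target_fraction}")
    plane = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(wt_region_mask, dtype=bool)
    if plane.shape != mask.shape:
        raise GeometryError("plane and wild-type mask shapes differ")
    vals = np.sort(plane[mask].ravel())
    n = vals.size
    if n == 0:
        raise GeometryError("wild-type region is empty")
    uniq = np.unique(vals)
    # candidate below the minimum admits the all-puncta solution at target 1
    candidates = np.concatenate(([uniq[0] - 1.0], uniq))
    frac_above = (n - np.searchsorted(vals, candidates, side="right")) / n
    ok = frac_above <= target_fraction   # monotone: False...False True...True
    first = int(np.argmax(ok))
    threshold = float(candidates[first])
    achieved = float(frac_above[first])
    if uniq.size == 1:
        warnings.warn("constant wild-type region: threshold at the constant, zero puncta",
                      stacklevel=2)
    return threshold, achieved


def extract_puncta(plane: np.ndarray, region_mask: np.ndarray, threshold: float,
                   min_area: int = 1, region: str = "") -> PunctaSet:
    """Above-threshold 8-connected components within a region.

    The threshold is taken as given (calibrated on wild-type elsewhere) —
    the mutant path never recalibrates.  Components smaller than
    ``min_area`` pixels are dropped.
    """
    plane = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(region_mask, dtype=bool)
    if plane.shape != mask.shape:
        raise GeometryError("plane and region mask shapes differ")
    if not np.isfinite(threshold):
        raise SpecError("threshold must be finite")
    above = (plane > threshold) & mask
    labeled, n_comp = ndimage.label(above, structure=_PUNCTA_CONNECTIVITY)
    region_area = int(mask.sum())
    achieved = float(above.sum()) / region_area if region_area else 0.0
    if n_comp == 0:
        return PunctaSet(threshold, achieved, region, region_area,
                         pd.DataFrame(columns=["area_px", "integrated_intensity",
                                               "mean_intensity", "centroid_row",
                                               "centroid_col"]))
    ids = np.arange(1, n_comp + 1)
    areas = ndimage.sum_labels(np.ones_like(plane), labeled, ids)
    sums = ndimage.sum_labels(plane, labeled, ids)
    coms = ndimage.center_of_mass(np.ones_like(plane), labeled, ids)
    frame = pd.DataFrame(
        {
            "area_px": areas.astype(int),
            "integrated_intensity": sums,
            "mean_intensity": sums / areas,
            "centroid_row": [r for r, _ in coms],
            "centroid_col": [c for _, c in coms],
        }
    )
    frame = frame[frame["area_px"] >= min_area].reset_index(drop=True)
    return PunctaSet(threshold, achieved, region, region_area, frame)


def puncta_ratio_tests(
    per_wing: list[tuple[PunctaSet, PunctaSet]],
) -> tuple[pd.DataFrame, dict[str, wstats.TestResult]]:
    """Mutant/wild-type puncta ratios per wing and one-sample t tests vs 1.0.

    ``per_wing`` holds (wild-type, mutant) PunctaSet pairs.  Count ratios
    are normalized per unit region area (clone and wild-type regions differ
    in size); size and intensity ratios compare per-punctum means.  Wings
    with no wild-type puncta are excluded with a warning.
    """
    rows = []
    for i, (wt, mut) in enumerate(per_wing):
        if wt.count == 0:
            warnings.warn(f"wing {i}: no wild-type puncta; ratio undefined, wing excluded",
                          stacklevel=2)
            continue
        rows.append(
            {
                "wing": i,
                "count_ratio": mut.density_per_kpx / wt.density_per_kpx,
                "area_ratio": mut.mean_of("area_px") / wt.mean_of("area_px"),
                "intensity_ratio": mut.mean_of("mean_intensity") / wt.mean_of("mean_intensity"),
            }
        )
    frame = pd.DataFrame(rows)
    tests: dict[str, wstats.TestResult] = {}
    for measure in ("count_ratio", "area_ratio", "intensity_ratio"):
        vals = frame[measure].dropna().to_numpy() if len(frame) else np.array([])
        if vals.size >= 2:
            tests[measure] = wstats.one_sample_t(vals, 1.0)
    return frame, tests
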