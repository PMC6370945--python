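"""Geometric front end: bright-slice selection, membrane skeletons and
per-cell boundary samples.

The membrane skeleton is the set of zero-label pixels that separate at least
two cells.  Each skeleton pixel is tagged with a genotype region: MUTANT only
if every adjacent cell lies in the mutant clone, WILDTYPE only if every
adjacent cell is wild-type, and EXCLUDED otherwise — junctions on the clone
border are shared between genotypes and are counted for neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, SpecError
from .imgio import CloneMap, ImageStack, LabelMask, Region

__all__ = [
    "BoundarySample",
    "MembraneSkeleton",
    "build_skeleton",
    "select_bright_slices",
    "sample_cell_boundary",
    "axial_angle_deg",
]

# 8-connected neighbourhood offsets, centre included
_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]


def axial_angle_deg(d_row: np.ndarray, d_col: np.ndarray) -> np.ndarray:
    """Axial (orientation, mod 180°) angle of displacement vectors.

    The convention is image-plane: 0° along increasing column, 90° along the
    row axis; the sign of the vector is irrelevant (axial data).
    """
    return np.degrees(np.arctan2(d_row, d_col)) % 180.0


@dataclass(frozen=True)
class BoundarySample:
    """One membrane pixel sampled for a cell's boundary."""

    pixel: tuple[int, int]
    intensity: float
    psi: float  # axial direction centroid -> pixel, degrees in [0, 180)
    cell_id: int


@dataclass
class MembraneSkeleton:
    """Region-tagged inter-cell membrane pixels with cell adjacency."""

    pixels: np.ndarray                     # (n, 2) int rows/cols
    adjacency: list[frozenset[int]]        # adjacent nonzero cell IDs per pixel
    region: np.ndarray                     # (n,) int8 Region codes
    shape: tuple[int, int]
    cell_centroids: dict[int, tuple[float, float]]
    cell_region: dict[int, int]
    _cell_index: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._cell_index:
            buckets: dict[int, list[int]] = {}
            for i, adj in enumerate(self.adjacency):
                for c in adj:
                    buckets.setdefault(c, []).append(i)
            self._cell_index = {c: np.asarray(ix) for c, ix in buckets.items()}

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixel_indices_for_cell(self, cell_id: int) -> np.ndarray:
        return self._cell_index.get(cell_id, np.empty(0, dtype=int))

    def region_mask(self, region: Region) -> np.ndarray:
        """Boolean image of skeleton pixels tagged with ``region``."""
        out = np.zeros(self.shape, dtype=bool)
        sel = self.region == int(region)
        out[self.pixels[sel, 0], self.pixels[sel, 1]] = True
        return out

    def membrane_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[self.pixels[:, 0], self.pixels[:, 1]] = True
        return out

    def overlay(self) -> np.ndarray:
        """Debug raster: region code + 1 at skeleton pixels, 0 elsewhere."""
        out = np.zeros(self.shape, dtype=np.uint8)
        out[self.pixels[:, 0], self.pixels[:, 1]] = self.region + 1
        return out


def _neighbour_labels(labels: np.ndarray) -> np.ndarray:
    """(9, rows, cols) array of 3x3-neighbourhood labels, zero-padded."""
    h, w = labels.shape
    padded = np.pad(labels, 1)
    return np.stack([padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w] for dr, dc in _OFFSETS])


def cell_centroids(label: LabelMask) -> dict[int, tuple[float, float]]:
    """Pixel-mean centroid (row, col) per cell."""
    ids = label.cell_ids
    if ids.size == 0:
        return {}
    coms = ndimage.center_of_mass(np.ones_like(label.labels), label.labels, ids)
    return {int(i): (float(r), float(c)) for i, (r, c) in zip(ids, coms)}


def build_skeleton(label: LabelMask, clone: CloneMap) -> MembraneSkeleton:
    """Extract the inter-cell membrane skeleton and tag each pixel by genotype.

    Membrane pixels are zero-label pixels whose 3x3 (8-connected)
    neighbourhood contains at least two distinct nonzero cell labels.  A
    cell's genotype is the clone-map code at its centroid; a skeleton pixel
    inherits MUTANT/WILDTYPE only when all adjacent cells agree, else
    EXCLUDED.
    """
    if label.shape != clone.shape:
        raise GeometryError(f"label shape {label.shape} != clone shape {clone.shape}")
    lab = label.labels
    neigh = _neighbour_labels(lab)
    zero = lab == 0
    rows, cols = np.nonzero(zero)
    vals = neigh[:, rows, cols]  # (9, m)

    pixels: list[tuple[int, int]] = []
    adjacency: list[frozenset[int]] = []
    for j in range(vals.shape[1]):
        ids = set(int(v) for v in vals[:, j])
        ids.discard(0)
        if len(ids) >= 2:
            pixels.append((int(rows[j]), int(cols[j])))
            adjacency.append(frozenset(ids))
    if not pixels:
        raise GeometryError("no membrane pixels: mask contains no inter-cell boundaries")

    centroids = cell_centroids(label)
    h, w = clone.shape
    cell_region: dict[int, int] = {}
    for cid, (r, c) in centroids.items():
        rr = min(max(int(round(r)), 0), h - 1)
        cc = min(max(int(round(c)), 0), w - 1)
        cell_region[cid] = int(clone.regions[rr, cc])

    region = np.empty(len(pixels), dtype=np.int8)
    for i, adj in enumerate(adjacency):
        tags = {cell_region[c] for c in adj}
        if tags == {int(Region.MUTANT)}:
            region[i] = int(Region.MUTANT)
        elif tags == {int(Region.WILDTYPE)}:
            region[i] = int(Region.WILDTYPE)
        else:
            region[i] = int(Region.EXCLUDED)

    return MembraneSkeleton(
        pixels=np.asarray(pixels, dtype=np.int64),
        adjacency=adjacency,
        region=region,
        shape=label.shape,
        cell_centroids=centroids,
        cell_region=cell_region,
    )


def select_bright_slices(
    stack: ImageStack,
    skeleton_or_mask: MembraneSkeleton | LabelMask | np.ndarray,
    k: int = 3,
) -> tuple[np.ndarray, list[int]]:
    """Average the ``k`` slices with highest mean membrane intensity.

    Brightness of a slice is its mean intensity over membrane pixels.  Ties
    are broken toward smaller z (more apical).  The chosen slices need not be
    consecutive.  Returns the pixelwise mean plane and the sorted chosen
    z indices.
    """
    if k < 1 or k > stack.n_slices:
        raise SpecError(f"k={k} outside [1, {stack.n_slices}]")
    if isinstance(skeleton_or_mask, MembraneSkeleton):
        memb = skeleton_or_mask.membrane_mask()
    elif isinstance(skeleton_or_mask, LabelMask):
        memb = skeleton_or_mask.labels == 0
    else:
        memb = np.asarray(skeleton_or_mask, dtype=bool)
    if memb.shape != stack.shape:
        raise GeometryError(f"membrane mask shape {memb.shape} != stack shape {stack.shape}")
    if not memb.any():
        raise GeometryError("membrane mask is empty")
    scores = stack.voxels[:, memb].mean(axis=1)
    # stable argsort of -scores keeps smaller z first among ties
    order = np.argsort(-scores, kind="stable")
    chosen = sorted(int(z) for z in order[:k])
    plane = stack.voxels[chosen].mean(axis=0)
    return plane, chosen


def sample_cell_boundary(
    plane: np.ndarray,
    label: LabelMask,
    cell_id: int,
    skeleton: MembraneSkeleton | None = None,
) -> list[BoundarySample]:
    """Sample a cell's adjacent membrane pixels from an intensity plane.

    Each sample carries the intensity at the pixel and the axial direction
    ``psi`` of the centroid-to-pixel vector (degrees, mod 180).  When no
    prebuilt skeleton is given one is derived from the label mask alone
    (uniform wild-type clone).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.shape != label.shape:
        raise GeometryError(f"plane shape {plane.shape} != mask shape {label.shape}")
    if cell_id not in set(int(i) for i in label.cell_ids):
        raise GeometryError(f"cell {cell_id} not present in label mask")
    if skeleton is None:
        skeleton = build_skeleton(label, CloneMap(np.ones(label.shape, dtype=np.int8)))
    idx = skeleton.pixel_indices_for_cell(cell_id)
    if idx.size == 0:
        raise GeometryError(f"cell {cell_id} has no adjacent membrane pixels")
    r0, c0 = skeleton.cell_centroids[cell_id]
    px = skeleton.pixels[idx]
    psi = axial_angle_deg(px[:, 0] - r0, px[:, 1] - c0)
    return [
        BoundarySample(
            pixel=(int(r), int(c)),
            intensity=float(plane[r, c]),
            psi=float(p),
            cell_id=int(cell_id),
        )
        for (r, c), p in zip(px, psi)
    ]
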