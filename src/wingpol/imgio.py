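"""Raster and table I/O plus the shared in-memory containers.

Conventions used throughout the package:

* raster coordinates are 0-based ``(row, col)``; z index is 0-based from the
  most apical slice;
* all angles are reported in degrees;
* intensities are carried as ``float64`` internally regardless of on-disk bit
  depth (quantile and fitting arithmetic needs floats);
* clone rasters use the fixed code ``0 = EXCLUDED, 1 = WILDTYPE, 2 = MUTANT``.

Downstream modules consume only the types defined here and never re-read
files themselves.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, GeometryError

__all__ = [
    "Region",
    "ImageStack",
    "LabelMask",
    "CloneMap",
    "read_stack",
    "write_stack",
    "read_masks",
    "write_mask",
    "write_results",
    "read_results",
]


class Region(enum.IntEnum):
    """Genotype region code; values match the on-disk clone-raster dialect."""

    EXCLUDED = 0
    WILDTYPE = 1
    MUTANT = 2


@dataclass
class ImageStack:
    """A z-ordered single-channel fluorescence stack.

    Parameters
    ----------
    voxels
        ``(z, rows, cols)`` array of non-negative intensities in arbitrary
        fluorescence units.
    pixel_size_um
        Lateral pixel pitch in micrometres.
    z_step_um
        Axial step between slices in micrometres.
    channel_name
        Free-text stain/channel identifier.
    """

    voxels: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None, :, :]
        if self.voxels.ndim != 3:
            raise FormatError(f"stack must be 2-D or 3-D, got ndim={self.voxels.ndim}")
        if self.voxels.shape[1] < 2 or self.voxels.shape[2] < 2:
            raise FormatError("spatial dimensions must be at least 2x2")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise FormatError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise FormatError("pixel_size_um and z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (rows, cols) shape of each slice."""
        return self.voxels.shape[1:]


@dataclass
class LabelMask:
    """Per-pixel cell identity: 0 = membrane/background, k >= 1 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise FormatError("label mask must hold integers")
            self.labels = as_int
        else:
            self.labels = self.labels.astype(np.int64)
        if np.any(self.labels < 0):
            raise FormatError("labels must be non-negative")

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted array of distinct nonzero labels (gaps preserved)."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CloneMap:
    """Per-pixel genotype region over {EXCLUDED, WILDTYPE, MUTANT}."""

    regions: np.ndarray

    def __post_init__(self) -> None:
        self.regions = np.asarray(self.regions)
        if self.regions.ndim != 2:
            raise FormatError("clone map must be 2-D")
        codes = np.unique(self.regions)
        valid = {int(r) for r in Region}
        unknown = set(int(c) for c in codes) - valid
        if unknown:
            raise FormatError(f"unknown clone codes {sorted(unknown)}; valid: {sorted(valid)}")
        self.regions = self.regions.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.regions.shape

    def mask(self, region: Region) -> np.ndarray:
        return self.regions == int(region)


# ---------------------------------------------------------------------------
# raster I/O

def _sidecar_metadata(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_stack(path: str | Path, *, pixel_size_um: float | None = None,
               z_step_um: float | None = None, channel_name: str | None = None) -> ImageStack:
    """Read a single-channel TIFF (single- or multi-page) as an :class:`ImageStack`.

    Metadata falls back to a ``<stem>.json`` sidecar next to the file, then to
    explicit keyword overrides, then to 1.0 / "".  RGB input is rejected: the
    pipeline's contract is one channel per file.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            if page.photometric == tifffile.PHOTOMETRIC.RGB or page.samplesperpixel >= 3:
                raise FormatError(f"{path}: RGB TIFF; expected single channel")
            arr = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # unreadable / not a TIFF
        raise FormatError(f"could not read raster {path}: {exc}") from exc
    meta = _sidecar_metadata(path)
    return ImageStack(
        voxels=arr,
        pixel_size_um=pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 1.0),
        z_step_um=z_step_um if z_step_um is not None else meta.get("z_step_um", 1.0),
        channel_name=channel_name if channel_name is not None else meta.get("channel_name", ""),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF plus a metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "pixel_size_um": stack.pixel_size_um,
                "z_step_um": stack.z_step_um,
                "channel_name": stack.channel_name,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def read_masks(label_path: str | Path, clone_path: str | Path) -> tuple[LabelMask, CloneMap]:
    """Read paired cell-label and clone rasters, enforcing shape agreement."""
    try:
        labels = tifffile.imread(label_path)
        clones = tifffile.imread(clone_path)
    except Exception as exc:
        raise FormatError(f"could not read mask rasters: {exc}") from exc
    label = LabelMask(labels)
    clone = CloneMap(clones)
    if label.shape != clone.shape:
        raise GeometryError(
            f"label mask shape {label.shape} != clone map shape {clone.shape}")
    return label, clone


def write_mask(mask: LabelMask | CloneMap, path: str | Path) -> None:
    arr = mask.labels if isinstance(mask, LabelMask) else mask.regions
    dtype = np.uint16 if arr.max(initial=0) < 2**16 else np.int32
    tifffile.imwrite(Path(path), arr.astype(dtype), photometric="minisblack")


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = ["wing_id", "genotype_region", "measure", "value"]


@dataclass
class ResultTable:
    """Tidy long-format measurement table (one row per wing/region/measure)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"result table missing columns {missing}")
        if len(self.frame):
            if self.frame["wing_id"].isna().any():
                raise FormatError("result table has missing wing_id")
            vals = pd.to_numeric(self.frame["value"], errors="coerce")
            if not np.all(np.isfinite(vals)):
                raise FormatError("result table values must be finite numbers")


def write_results(table: ResultTable | pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table as CSV with a stable column order and
    reproducible float formatting (repr-roundtrip precision)."""
    frame = table.frame if isinstance(table, ResultTable) else table
    cols = [c for c in RESULT_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame = frame[cols]
    frame.to_csv(Path(path), index=False, float_format="%.12g", lineterminator="\n")


def read_results(path: str | Path) -> ResultTable:
    return ResultTable(pd.read_csv(Path(path)))
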