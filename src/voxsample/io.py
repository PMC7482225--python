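"""Reading and writing external formats.

Handles multi-page TIFF stacks (one grayscale channel per stack), the sample
table written as CSV, plain-text region-of-interest files, and integer-labeled
cell-mask volumes.

Conventions owned by this module
--------------------------------
* Arrays are indexed ``(z, y, x)``; the voxel at index ``(k, j, i)`` has its
  centre at ``(k*sz, j*sy, i*sx)`` micrometres (0-based indices).
* All public coordinates in files are micrometres and ordered ``x y z`` for
  user familiarity; the (z, y, x) <-> (x, y, z) conversion happens here and
  nowhere else.
* Integer pixel data are converted to floating point *without rescaling*: a
  16-bit value of 65535 stays 65535.0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class Volume:
    """A single-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Non-negative, finite intensities. Integer input is converted to
        float64 without rescaling.
    spacing : (sz, sy, sx)
        Physical size of one voxel along each axis, micrometres.
    channel_name : str
        Free-text channel label (e.g. ``"dapi"``).
    """

    data: np.ndarray
    spacing: tuple
    channel_name: str = ""

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"volume must be 3D, got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise FormatError("every volume dimension must be >= 1")
        if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
            arr = arr.astype(np.float64)
        if not np.all(np.isfinite(arr)):
            raise FormatError("volume intensities must be finite")
        if arr.min() < 0:
            raise FormatError("volume intensities must be non-negative")
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    def axis_coords_um(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (µm)."""
        return np.arange(self.data.shape[axis]) * self.spacing[axis]


@dataclass
class LabeledMask:
    """Integer-labeled cell volume: 0 = background, k >= 1 = cell k."""

    labels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise FormatError("mask labels must be integers")
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise FormatError("mask labels must be non-negative")
        self.labels = arr.astype(np.int64)
        self.spacing = tuple(float(s) for s in self.spacing)

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class ROISet:
    """User regions of interest: isolated 3D points and 3D polylines.

    ``rois`` preserves file order as ``("point", (3,) array)`` /
    ``("line", (N, 3) array)`` entries, coordinates in µm, (z, y, x) order
    internally (files use x y z).
    """

    rois: list = field(default_factory=list)

    @property
    def points(self):
        return [c for kind, c in self.rois if kind == "point"]

    @property
    def polylines(self):
        return [c for kind, c in self.rois if kind == "line"]

    def __len__(self):
        return len(self.rois)


def read_stack(path, spacing, channel_name: str = "") -> Volume:
    """Read a multi-page TIFF, or a directory of single-page TIFFs in
    lexicographic filename order, as one Volume (z = page index)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(os.fspath(p)) for p in files]
    else:
        data = tifffile.imread(os.fspath(path))
        if data.ndim == 2:
            pages = [data]
        elif data.ndim == 3:
            pages = list(data)
        else:
            raise FormatError(f"unsupported TIFF dimensionality {data.ndim}")
    if len(pages) == 0:
        raise FormatError(f"{path}: zero pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: pages of differing shapes {sorted(shapes)}")
    stack = np.stack(pages, axis=0)
    return Volume(stack, spacing, channel_name=channel_name)


def write_stack(data, path) -> None:
    """Write a 3D array (or Volume) as a multi-page TIFF, preserving dtype."""
    if isinstance(data, Volume):
        data = data.data
    arr = np.asarray(data)
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")


def read_mask(path, spacing) -> LabeledMask:
    """Read an integer-labeled cell mask stored as a TIFF stack."""
    vol = tifffile.imread(os.fspath(path))
    if vol.ndim == 2:
        vol = vol[None]
    return LabeledMask(np.asarray(vol), spacing)


def read_roi(path) -> ROISet:
    """Parse the plain-text ROI dialect.

    Each non-blank, non-comment line is either ``point x y z`` or
    ``line x1 y1 z1 x2 y2 z2 ...`` with coordinates in micrometres.
    """
    rois = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            kind, vals = tokens[0].lower(), tokens[1:]
            try:
                nums = [float(v) for v in vals]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if kind == "point":
                if len(nums) != 3:
                    raise FormatError(f"{path}:{lineno}: point needs exactly 3 values")
                x, y, z = nums
                rois.append(("point", np.array([z, y, x])))
            elif kind == "line":
                if len(nums) < 6 or len(nums) % 3:
                    raise FormatError(
                        f"{path}:{lineno}: line needs >= 2 vertices (multiples of 3 values)"
                    )
                xyz = np.array(nums).reshape(-1, 3)
                rois.append(("line", xyz[:, ::-1].copy()))  # -> (z, y, x)
            else:
                raise FormatError(f"{path}:{lineno}: unknown ROI kind {kind!r}")
    return ROISet(rois)


_LEADING = ["object_type", "object_id", "x_um", "y_um", "z_um", "radius_um"]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten SampleRecord-like objects into a tidy DataFrame.

    Column order: identity/coordinates first, measurement columns in sorted
    order, geometry distances last. Missing measurements become NaN (empty
    cells in the CSV).
    """
    rows = [r.to_row() for r in records]
    keys = set()
    for row in rows:
        keys.update(row)
    trailing = sorted(k for k in keys if k.startswith("distance_to_"))
    middle = sorted(k for k in keys if k not in _LEADING and k not in trailing)
    columns = [c for c in _LEADING if c in keys or not rows] + middle + trailing
    if not rows:
        columns = list(_LEADING)
    return pd.DataFrame(rows, columns=columns)


def write_samples_csv(records: Sequence, path) -> None:
    """Write detected-object measurement rows as CSV (header always present)."""
    records_to_frame(records).to_csv(path, index=False)


def read_samples_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
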