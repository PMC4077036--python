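"""Core data types and file I/O for the nuclei-segmentation pipeline.

Images are 3D fluorescence stacks stored as multi-page grayscale TIFF, one
stack per time point, with anisotropic voxel spacing (default 0.25 x 0.25 x
1 um, i.e. z is four times coarser than xy).  Internally stacks are float
arrays in ``(z, y, x)`` axis order with intensities normalized to [0, 1];
TIFF pages map to z-slices.  All physical coordinates are micrometres, with
``coordinate = voxel index * spacing`` (0-based indices, voxel centers).

Point tables (ground-truth nucleus centers, detections) are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSpacing",
    "ImageStack",
    "ImageSeries",
    "LabelVolume",
    "GroundTruth",
    "NucleusDetection",
    "FormatError",
    "read_image_series",
    "read_ground_truth",
    "write_ground_truth",
    "write_detections",
    "read_detections",
    "write_labels",
    "read_labels",
    "write_image_stack",
]

DEFAULT_SPACING = (0.25, 0.25, 1.0)


class FormatError(ValueError):
    """Raised when an input table or image violates the expected format."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel in micrometres per axis."""

    dx: float = 0.25
    dy: float = 0.25
    dz: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing in array axis order (z, y, x)."""
        return (self.dz, self.dy, self.dx)


@dataclass
class ImageStack:
    """One 3D intensity stack with its physical voxel spacing.

    ``intensities`` is (z, y, x) ordered and finite.  Stacks read from
    file or rendered synthetically are nonnegative in [0, 1]; filtered
    stacks (band-pass responses) may carry signed values.
    """

    intensities: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"stack must be 3D with >=1 voxel per axis, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("stack intensities must be finite")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def physical_size(self) -> tuple[float, float, float]:
        """Extent of the volume in um, (z, y, x)."""
        nz, ny, nx = self.shape
        return (nz * self.spacing.dz, ny * self.spacing.dy, nx * self.spacing.dx)


@dataclass
class ImageSeries:
    """Time-ordered stacks sharing shape and spacing; ``dt`` in minutes."""

    frames: list[ImageStack]
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("series needs at least one frame")
        if self.dt <= 0:
            raise ValueError(f"frame interval must be positive, got {self.dt}")
        shape0, spacing0 = self.frames[0].shape, self.frames[0].spacing
        for i, f in enumerate(self.frames):
            if f.shape != shape0:
                raise ValueError(
                    f"frame {i} shape {f.shape} differs from frame 0 shape {shape0}"
                )
            if f.spacing != spacing0:
                raise ValueError(f"frame {i} spacing differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, t: int) -> ImageStack:
        return self.frames[t]

    @property
    def spacing(self) -> VoxelSpacing:
        return self.frames[0].spacing


@dataclass
class LabelVolume:
    """Integer-labeled segmentation aligned with one stack; 0 = background.

    After any segmentation operation positive labels form the contiguous
    set ``1..K``.
    """

    labels: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be integers")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.labels = arr.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass(frozen=True)
class NucleusDetection:
    """One segmented nucleus: label, centroid in um (x, y, z), voxel count."""

    label: int
    centroid: tuple[float, float, float]
    voxels: int

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("label must be positive")
        if self.voxels < 1:
            raise ValueError("voxel count must be >= 1")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=np.float64)


class GroundTruth:
    """Reference nucleus centers per time point.

    Maps frame index -> array of (id, x, y, z) rows, coordinates in um.
    Ids must be unique within a time point.
    """

    def __init__(self, points: Mapping[int, Sequence[tuple[int, float, float, float]]] | None = None):
        self._points: dict[int, list[tuple[int, float, float, float]]] = {}
        if points:
            for t, rows in points.items():
                for pid, x, y, z in rows:
                    self.add(int(t), int(pid), float(x), float(y), float(z))

    def add(self, t: int, pid: int, x: float, y: float, z: float) -> None:
        rows = self._points.setdefault(t, [])
        if any(r[0] == pid for r in rows):
            raise FormatError(f"duplicate ground-truth id {pid} at t={t}")
        rows.append((pid, x, y, z))

    def frames(self) -> list[int]:
        return sorted(self._points)

    def ids(self, t: int) -> list[int]:
        return [r[0] for r in self._points.get(t, [])]

    def coords(self, t: int) -> np.ndarray:
        """(n, 3) array of (x, y, z) um positions at frame t (input order)."""
        rows = self._points.get(t, [])
        if not rows:
            return np.empty((0, 3), dtype=np.float64)
        return np.asarray([r[1:] for r in rows], dtype=np.float64)

    def count(self, t: int) -> int:
        return len(self._points.get(t, []))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        if self.frames() != other.frames():
            return False
        return all(
            sorted(self._points[t]) == sorted(other._points[t]) for t in self.frames()
        )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _normalize_intensities(arr: np.ndarray) -> np.ndarray:
    """Scale integer images to [0, 1] by the format maximum; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    return arr.astype(np.float64)


def _read_stack(path: str | Path, spacing: VoxelSpacing) -> ImageStack:
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page grayscale TIFF, got ndim={arr.ndim}")
    return ImageStack(_normalize_intensities(arr), spacing)


def read_image_series(
    paths: Iterable[str | Path],
    spacing: VoxelSpacing | None = None,
    dt: float = 1.0,
) -> ImageSeries:
    """Read an ordered list of multi-page TIFFs into one time series.

    All stacks must share dimensions; intensities are normalized to [0, 1]
    (lossless for a fixed bit depth: the scale factor is the dtype maximum).
    """
    spacing = spacing or VoxelSpacing()
    frames = [_read_stack(p, spacing) for p in paths]
    if not frames:
        raise ValueError("no input paths given")
    shape0 = frames[0].shape
    for p, f in zip(paths, frames):
        if f.shape != shape0:
            raise ValueError(f"stack {p} shape {f.shape} differs from first stack {shape0}")
    return ImageSeries(frames, dt=dt)


def write_image_stack(stack: ImageStack, path: str | Path, dtype=np.uint16) -> None:
    """Write a [0, 1] stack as a multi-page integer TIFF (page order = z)."""
    info = np.iinfo(dtype)
    arr = np.clip(np.rint(stack.intensities * info.max), 0, info.max).astype(dtype)
    tifffile.imwrite(str(path), arr)


def write_labels(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as multi-page 16-bit TIFF, pages in z order."""
    if vol.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError(
            f"max label {vol.labels.max()} does not fit 16-bit TIFF"
        )
    tifffile.imwrite(str(path), vol.labels.astype(np.uint16))


def read_labels(path: str | Path, spacing: VoxelSpacing | None = None) -> LabelVolume:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelVolume(arr.astype(np.int32), spacing or VoxelSpacing())


# ---------------------------------------------------------------------------
# CSV point tables
# ---------------------------------------------------------------------------

_GT_COLUMNS = ["t", "id", "x_um", "y_um", "z_um"]
_DET_COLUMNS = ["t", "label", "x_um", "y_um", "z_um", "voxels"]


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read reference nucleus centers from CSV with header t,id,x_um,y_um,z_um."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise OSError(f"cannot read ground truth {path}: {exc}") from exc
    missing = [c for c in _GT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected {_GT_COLUMNS}")
    gt = GroundTruth()
    for row in df.itertuples(index=False):
        try:
            t, pid = int(row.t), int(row.id)
            x, y, z = float(row.x_um), float(row.y_um), float(row.z_um)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric value in row {tuple(row)}") from exc
        if not np.isfinite([x, y, z]).all():
            raise FormatError(f"{path}: non-finite coordinate in row {tuple(row)}")
        gt.add(t, pid, x, y, z)
    return gt


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    rows = [
        (t, pid, x, y, z)
        for t in gt.frames()
        for (pid, x, y, z) in gt._points[t]
    ]
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def write_detections(dets: Mapping[int, Sequence[NucleusDetection]], path: str | Path) -> None:
    """Write per-frame detections as CSV with columns t,label,x_um,y_um,z_um,voxels."""
    rows = [
        (t, d.label, d.centroid[0], d.centroid[1], d.centroid[2], d.voxels)
        for t in sorted(dets)
        for d in dets[t]
    ]
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_detections(path: str | Path) -> dict[int, list[NucleusDetection]]:
    df = pd.read_csv(path)
    missing = [c for c in _DET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected {_DET_COLUMNS}")
    out: dict[int, list[NucleusDetection]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.t), []).append(
            NucleusDetection(
                label=int(row.label),
                centroid=(float(row.x_um), float(row.y_um), float(row.z_um)),
                voxels=int(row.voxels),
            )
        )
    return out
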