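"""Medical volume and mesh I/O.

The package-wide carrier for 3D image data is :class:`Volume`: a scalar
voxel grid plus the geometric metadata (spacing, origin) needed to map
voxel indices to world millimetres.  Arrays are indexed ``(slice, row,
column)`` — i.e. ``(z, y, x)`` — and ``spacing`` / ``origin`` are stored
in that same axis order.  The world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``.  Direction cosines are assumed
axis-aligned; oblique acquisitions are reoriented on read.

Supported external formats: DICOM series (read), NIfTI-1 (read/write),
STL and Wavefront OBJ surface meshes (write).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

__all__ = [
    "Volume",
    "LabelVolume",
    "SurfaceMesh",
    "FormatError",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "read_label_nifti",
    "write_label_nifti",
    "resample_isotropic",
    "resample_to_shape",
    "resample_onto",
    "crop_to_content",
    "write_mesh",
]

#: Default legend for label volumes.
DEFAULT_LEGEND = {0: "background", 1: "vessel", 2: "aneurysm"}


class FormatError(ValueError):
    """Raised when an input file or directory is not a readable volume."""


@dataclass
class Volume:
    """A 3D scalar image with grid geometry.

    Parameters
    ----------
    data:
        3D array of intensities, indexed ``(z, y, x)``.
    spacing:
        Voxel size in mm along each axis, ``(z, y, x)`` order.
    origin:
        World position (mm) of voxel ``(0, 0, 0)``, ``(z, y, x)`` order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new voxel values (shape must match)."""
        if np.shape(data)[:3] != self.data.shape:
            raise ValueError("with_data requires matching shape")
        return replace(self, data=np.asarray(data))

    def index_to_world(self, index) -> np.ndarray:
        """World mm coordinates of a (fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelVolume:
    """Integer label mask sharing a parent :class:`Volume`'s grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from legend")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, role: str) -> np.ndarray:
        """Binary mask of all voxels whose legend entry equals ``role``."""
        keys = [k for k, v in self.legend.items() if v == role]
        return np.isin(self.labels, keys)

    def as_volume(self) -> Volume:
        return Volume(self.labels.astype(np.float32), self.spacing, self.origin)


@dataclass
class SurfaceMesh:
    """Triangle mesh in world millimetres."""

    vertices: np.ndarray  # (n, 3) float, world mm
    faces: np.ndarray  # (m, 3) int vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def validate(self) -> None:
        n = len(self.vertices)
        if n == 0 or len(self.faces) == 0:
            raise ValueError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face index out of range")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("degenerate face (repeated vertex index)")

    def euler_characteristic(self) -> int:
        edges = np.sort(
            np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.faces)

    def is_watertight(self) -> bool:
        edges = np.sort(
            np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def area(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)


# --- SimpleITK bridge -------------------------------------------------------
# SimpleITK orders spacing/origin (x, y, z); arrays come back (z, y, x).


def _from_sitk(img: sitk.Image) -> Volume:
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError("non-scalar pixel data")
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D image, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-3):
        # Oblique/flipped acquisition: reorient to the closest axis-aligned grid.
        img = sitk.DICOMOrient(img, "LPS")
    data = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(data, spacing, origin)


def _to_sitk(v: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data))
    img.SetSpacing(tuple(reversed(v.spacing)))
    img.SetOrigin(tuple(reversed(v.origin)))
    return img


# --- Readers / writers ------------------------------------------------------


def read_dicom_series(directory: os.PathLike | str) -> Volume:
    """Read a single-series DICOM stack into a :class:`Volume`.

    Slices are sorted by their position along the slice axis regardless of
    file naming.  Raises :class:`FormatError` for an empty directory, a
    directory holding more than one series, or non-scalar pixel data.
    """
    directory = str(directory)
    if not os.path.isdir(directory):
        raise FormatError(f"not a directory: {directory}")
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(directory)
    if len(series_ids) == 0:
        raise FormatError(f"no DICOM series found in {directory}")
    if len(series_ids) > 1:
        raise FormatError(f"directory holds {len(series_ids)} series; expected one")
    files = reader.GetGDCMSeriesFileNames(directory, series_ids[0])
    reader.SetFileNames(files)
    try:
        img = reader.Execute()
    except RuntimeError as exc:  # pragma: no cover - GDCM error text varies
        raise FormatError(f"failed to read DICOM series: {exc}") from exc
    return _from_sitk(img)


def read_nifti(path: os.PathLike | str) -> Volume:
    """Read a NIfTI-1 volume (.nii or .nii.gz)."""
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise FormatError(f"failed to read NIfTI file {path}: {exc}") from exc
    return _from_sitk(img)


def write_nifti(v: Volume, path: os.PathLike | str) -> None:
    """Write a volume as NIfTI-1; ``read_nifti`` round-trips it losslessly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(v), str(path))


def read_label_nifti(
    path: os.PathLike | str, legend: dict[int, str] | None = None
) -> LabelVolume:
    v = read_nifti(path)
    return LabelVolume(
        np.rint(v.data).astype(np.int16),
        v.spacing,
        v.origin,
        legend=dict(legend or DEFAULT_LEGEND),
    )


def write_label_nifti(lv: LabelVolume, path: os.PathLike | str) -> None:
    write_nifti(Volume(lv.labels.astype(np.int16), lv.spacing, lv.origin), path)


# --- Geometry operations ----------------------------------------------------


def _resample(v: Volume, new_shape, new_spacing, mode: str) -> Volume:
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    img = _to_sitk(Volume(v.data.astype(np.float64), v.spacing, v.origin))
    out = sitk.Resample(
        img,
        tuple(int(n) for n in reversed(new_shape)),
        sitk.Transform(),
        interp,
        tuple(reversed(v.origin)),
        tuple(float(s) for s in reversed(new_spacing)),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out)
    if mode == "nearest" or np.issubdtype(v.data.dtype, np.integer):
        data = np.rint(data).astype(v.data.dtype)
    else:
        data = data.astype(v.data.dtype)
    return Volume(data, tuple(new_spacing), v.origin)


def resample_isotropic(v: Volume, target_spacing: float, mode: str = "linear") -> Volume:
    """Resample onto a cubic-voxel grid of ``target_spacing`` mm.

    New axis lengths are ``round(old_len * old_spacing / target)`` (at least
    1), preserving the physical extent to within one voxel.  Use
    ``mode='nearest'`` for label data so no new label values appear.
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    if np.allclose(v.spacing, target_spacing):
        return replace(v, data=v.data.copy())
    new_shape = tuple(
        max(1, int(round(n * s / target_spacing)))
        for n, s in zip(v.shape, v.spacing)
    )
    return _resample(v, new_shape, (target_spacing,) * 3, mode)


def resample_to_shape(v: Volume, shape: tuple[int, int, int], mode: str = "linear") -> Volume:
    """Resample to an exact voxel shape, keeping the physical extent.

    The output spacing along each axis becomes ``extent / new_len``, so the
    grid may be anisotropic; used to force fixed-size network blocks.
    """
    new_spacing = tuple(
        n * s / t for n, s, t in zip(v.shape, v.spacing, shape)
    )
    return _resample(v, shape, new_spacing, mode)


def resample_onto(v: Volume, like: Volume, mode: str = "linear") -> Volume:
    """Resample ``v`` onto the exact grid (shape, spacing, origin) of ``like``."""
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    img = _to_sitk(Volume(v.data.astype(np.float64), v.spacing, v.origin))
    out = sitk.Resample(
        img,
        tuple(int(n) for n in reversed(like.shape)),
        sitk.Transform(),
        interp,
        tuple(reversed(like.origin)),
        tuple(float(s) for s in reversed(like.spacing)),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out)
    if mode == "nearest" or np.issubdtype(v.data.dtype, np.integer):
        data = np.rint(data).astype(v.data.dtype)
    else:
        data = data.astype(v.data.dtype)
    return Volume(data, like.spacing, like.origin)


def crop_to_content(v: Volume, background_threshold: float = 0.0) -> Volume:
    """Crop to the tight bounding box of voxels strictly above threshold.

    The origin is shifted so retained voxels keep their world coordinates.
    Raises ``ValueError`` if no voxel exceeds the threshold.
    """
    if not np.isfinite(background_threshold):
        raise ValueError("background_threshold must be finite")
    content = np.argwhere(v.data > background_threshold)
    if content.size == 0:
        raise ValueError("empty content: no voxel above threshold")
    lo = content.min(axis=0)
    hi = content.max(axis=0) + 1
    data = v.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    origin = tuple(np.asarray(v.origin) + lo * np.asarray(v.spacing))
    return Volume(data, v.spacing, origin)


def crop_like(lv: LabelVolume, cropped: Volume, original: Volume) -> LabelVolume:
    """Apply to ``lv`` the same crop that turned ``original`` into ``cropped``."""
    lo = np.rint(
        (np.asarray(cropped.origin) - np.asarray(original.origin))
        / np.asarray(original.spacing)
    ).astype(int)
    hi = lo + np.asarray(cropped.shape)
    labels = lv.labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    return LabelVolume(labels, lv.spacing, cropped.origin, legend=dict(lv.legend))


def write_mesh(m: SurfaceMesh, path: os.PathLike | str, format: str | None = None) -> None:
    """Write a surface mesh as STL or OBJ (chosen from ``format`` or suffix)."""
    m.validate()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("STL", "OBJ"):
        raise ValueError(f"unsupported mesh format: {fmt}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)
    tm.export(str(path), file_type=fmt.lower())
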