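"""Volumes, masks and landmarks: containers, NIfTI/CSV I/O, resampling, windowing.

All grids are axis-aligned: ``world_mm = origin + index * spacing`` with
0-based voxel indices and array axes ordered (x, y, z). Oblique orientations
are out of scope; headers with non-diagonal rotation parts are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "Landmark",
    "LandmarkSet",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_landmarks",
    "save_landmarks",
    "resample_isotropic",
    "crop_z",
    "apply_window",
]


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities — Hounsfield units before display windowing,
        dimensionless [0, 1] display units after.
    spacing : array-like of 3 floats
        Voxel size in mm per axis; strictly positive.
    origin : array-like of 3 floats
        World-mm coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be 3-vectors")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (…, 3) to continuous voxel coordinates."""
        return (np.asarray(xyz_mm, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, dtype=float) * self.spacing + self.origin

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid carrying ``data``."""
        return ImageVolume(data, self.spacing.copy(), self.origin.copy())


@dataclasses.dataclass
class BinaryMask:
    """A boolean voxel mask aligned to an ``ImageVolume`` grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.all(self.spacing > 0):
            raise ValueError("mask spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass(frozen=True)
class Landmark:
    label: str
    side: str  # "right" | "left"
    depth: str  # "proximal" | "distal"
    xyz: tuple[float, float, float]  # world mm


class LandmarkSet:
    """Labeled anatomical points (vessel bifurcations) in world mm.

    Labels are unique; pairing across time points is strictly by label.
    """

    def __init__(self, points: Iterable[Landmark]):
        self.points: list[Landmark] = list(points)
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate landmark labels: {dupes}")
        coords = np.array([p.xyz for p in self.points], dtype=float).reshape(-1, 3)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def coordinates(self) -> np.ndarray:
        """(n, 3) world-mm coordinates in point order."""
        return np.array([p.xyz for p in self.points], dtype=float).reshape(-1, 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.points],
                "side": [p.side for p in self.points],
                "depth": [p.depth for p in self.points],
                "x": [p.xyz[0] for p in self.points],
                "y": [p.xyz[1] for p in self.points],
                "z": [p.xyz[2] for p in self.points],
            }
        )

    def with_coordinates(self, xyz: np.ndarray) -> "LandmarkSet":
        """Same labels/metadata with replaced world coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.points), 3):
            raise ValueError("coordinate array shape mismatch")
        return LandmarkSet(
            Landmark(p.label, p.side, p.depth, tuple(map(float, q)))
            for p, q in zip(self.points, xyz)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from_geometry(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_nifti(img: nib.Nifti1Image, path) -> tuple[np.ndarray, np.ndarray]:
    aff = img.affine
    rot = aff[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"{path}: header spacing invalid or zero: {spacing}")
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > 1e-3 * spacing.max():
        raise ValueError(f"{path}: oblique orientation not supported (non-diagonal affine)")
    if np.any(np.diag(rot) < 0):
        raise ValueError(f"{path}: flipped axes not supported; reorient to RAS first")
    return spacing, aff[:3, 3].copy()


def load_volume(path) -> ImageVolume:
    """Read a scalar volume from a NIfTI-1 file.

    Fails hard (naming the offending field) on zero/missing spacing rather
    than guessing geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing, origin = _geometry_from_nifti(img, path)
    return ImageVolume(data, spacing, origin)


def save_volume(vol: ImageVolume, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=dtype),
        _affine_from_geometry(vol.spacing, vol.origin),
    )
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def load_mask(path) -> BinaryMask:
    vol = load_volume(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin)


def save_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8),
        _affine_from_geometry(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Landmark CSV dialect: header label,side,depth,x,y,z (world mm)

_LANDMARK_COLUMNS = ["label", "side", "depth", "x", "y", "z"]


def load_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    return LandmarkSet(
        Landmark(str(r.label), str(r.side), str(r.depth), (float(r.x), float(r.y), float(r.z)))
        for r in df.itertuples()
    )


def save_landmarks(points: LandmarkSet, path) -> None:
    points.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def resample_isotropic(vol: ImageVolume, target_spacing: float = 1.0) -> ImageVolume:
    """Resample to an isotropic grid by trilinear interpolation.

    Output shape is ``ceil(extent_mm / target_spacing)`` per axis so the full
    physical extent is retained; samples falling outside the input grid take
    the volume minimum (air in windowed CT).
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    if np.allclose(vol.spacing, target_spacing):
        return ImageVolume(vol.data.copy(), vol.spacing.copy(), vol.origin.copy())
    extent = np.asarray(vol.shape) * vol.spacing
    out_shape = np.ceil(extent / target_spacing - 1e-9).astype(int)
    grids = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(out_shape, vol.spacing)],
        indexing="ij",
    )
    fill = float(vol.data.min())
    data = ndimage.map_coordinates(
        vol.data, np.stack(grids), order=1, mode="constant", cval=fill
    )
    return ImageVolume(data, np.full(3, float(target_spacing)), vol.origin.copy())


def crop_z(vol: ImageVolume, z_range: tuple[int, int]) -> ImageVolume:
    """Keep axial slices ``z_range[0]:z_range[1]`` (half-open, voxel indices).

    Lung-extent selection is the caller's responsibility (e.g. the slices
    covering the lungs); nothing is inferred from the image.
    """
    z0, z1 = int(z_range[0]), int(z_range[1])
    if not (0 <= z0 < z1 <= vol.shape[2]):
        raise ValueError(f"z_range {z_range} outside volume with {vol.shape[2]} slices")
    origin = vol.origin + np.array([0.0, 0.0, z0 * vol.spacing[2]])
    return ImageVolume(vol.data[:, :, z0:z1].copy(), vol.spacing.copy(), origin)


def apply_window(vol: ImageVolume, level: float = -600.0, width: float = 600.0) -> ImageVolume:
    """CT display windowing: map HU in [level−width/2, level+width/2] → [0, 1].

    The defaults are the lung window used before registration. The map is
    linear inside the window and clipped outside; it is monotone
    non-decreasing in HU.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = level - width / 2.0
    out = np.clip((vol.data - lo) / width, 0.0, 1.0)
    return vol.like(out)
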