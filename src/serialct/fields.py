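"""Dense deformation-field algebra: warping, composition, inversion, Jacobians.

A :class:`DeformationField` stores the map φ on the fixed (time-1) grid as a
displacement ``u`` in voxel units, ``φ(x) = x + u(x)``, and maps fixed-grid
coordinates to moving-image (time-2) coordinates. ``det(Dφ) > 1`` therefore
means local growth over time.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume, LandmarkSet

__all__ = [
    "DeformationField",
    "JacobianMap",
    "identity_field",
    "warp_image",
    "warp_mask",
    "compose",
    "jacobian_determinant",
    "warp_points",
    "invert",
    "InversionError",
    "save_field",
    "load_field",
    "save_jacobian",
]


class InversionError(RuntimeError):
    """Fixed-point inversion failed to converge (field likely not diffeomorphic)."""


@dataclasses.dataclass
class DeformationField:
    """Dense map φ(x) = x + u(x) on the fixed grid (voxel units)."""

    u: np.ndarray  # (3, nx, ny, nz) displacement, voxel units
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(f"displacement must have shape (3, nx, ny, nz), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]  # type: ignore[return-value]

    def max_displacement(self) -> float:
        """Largest displacement magnitude in voxels."""
        return float(np.sqrt((self.u.astype(np.float64) ** 2).sum(axis=0)).max())


@dataclasses.dataclass
class JacobianMap:
    """Voxelwise det(Dφ) on the fixed grid: >1 growth, <1 shrinkage, 1 unchanged."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def min_interior(self) -> float:
        """Minimum determinant over interior voxels (boundary one-sided stencils excluded)."""
        core = self.data[1:-1, 1:-1, 1:-1]
        return float(core.min()) if core.size else float(self.data.min())


def identity_field(shape, spacing=None, origin=None) -> DeformationField:
    shape = tuple(int(n) for n in shape)
    spacing = np.ones(3) if spacing is None else np.asarray(spacing, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    return DeformationField(np.zeros((3, *shape), dtype=np.float32), spacing, origin)


def _grid_coords(shape) -> np.ndarray:
    """(3, nx, ny, nz) array of voxel index coordinates."""
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    )


def _sample_vector(field: np.ndarray, coords: np.ndarray, mode: str = "nearest") -> np.ndarray:
    """Trilinearly sample each component of a (3, …) vector field at voxel coords."""
    return np.stack(
        [ndimage.map_coordinates(field[c], coords, order=1, mode=mode) for c in range(3)]
    )


def warp_image(vol: ImageVolume, phi: DeformationField, fill: float | None = None) -> ImageVolume:
    """Pull back ``vol`` through φ: ``out(x) = vol(φ(x))``, trilinear.

    Out-of-grid samples take ``fill`` (default: the volume minimum, i.e. air).
    """
    if vol.shape != phi.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs field {phi.shape}")
    coords = _grid_coords(phi.shape) + phi.u
    cval = float(vol.data.min()) if fill is None else float(fill)
    data = ndimage.map_coordinates(vol.data, coords, order=1, mode="constant", cval=cval)
    return vol.like(data)


def warp_mask(mask: BinaryMask, phi: DeformationField, threshold: float = 0.5) -> BinaryMask:
    """Pull a binary mask back through φ with partial-volume interpolation.

    The mask is interpolated as a [0, 1] occupancy image and re-thresholded,
    which is more volume-stable than nearest-neighbour sampling.
    """
    if mask.shape != phi.shape:
        raise ValueError("grid mismatch between mask and field")
    coords = _grid_coords(phi.shape) + phi.u
    occ = ndimage.map_coordinates(
        mask.data.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return BinaryMask(occ >= threshold, mask.spacing, mask.origin)


def compose(phi_outer: DeformationField, phi_inner: DeformationField) -> DeformationField:
    """(φ_outer ∘ φ_inner)(x) = φ_outer(φ_inner(x)).

    The outer displacement is sampled trilinearly at the inner map's output;
    outside the grid it is edge-extrapolated.
    """
    if phi_outer.shape != phi_inner.shape:
        raise ValueError("grid mismatch between fields")
    coords = _grid_coords(phi_inner.shape) + phi_inner.u
    u = phi_inner.u + _sample_vector(phi_outer.u, coords)
    return DeformationField(u, phi_inner.spacing, phi_inner.origin)


def jacobian_determinant(phi: DeformationField) -> JacobianMap:
    """det of the central-difference gradient of φ (one-sided at faces).

    Displacements and derivatives are taken in voxel units; because the grid
    is axis-aligned, det(I + ∂u/∂x) is identical in physical units for any
    (an)isotropic spacing.
    """
    grads = np.empty((3, 3, *phi.shape), dtype=np.float64)
    for c in range(3):
        gx, gy, gz = np.gradient(phi.u[c].astype(np.float64), edge_order=1)
        grads[c, 0], grads[c, 1], grads[c, 2] = gx, gy, gz
    for c in range(3):
        grads[c, c] += 1.0  # Dφ = I + Du
    a = grads
    det = (
        a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
        - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
        + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0])
    )
    return JacobianMap(det, phi.spacing, phi.origin)


def warp_points(points: LandmarkSet, phi: DeformationField) -> LandmarkSet:
    """Map landmarks (world mm) through φ by trilinear interpolation of u.

    Points outside the grid are flagged with a warning (displacement is
    edge-extrapolated), never silently dropped. Labels are preserved.
    """
    xyz = points.coordinates()
    vox = (xyz - phi.origin) / phi.spacing
    shape = np.asarray(phi.shape)
    outside = np.any((vox < 0) | (vox > shape - 1), axis=1)
    if outside.any():
        bad = [p.label for p, o in zip(points, outside) if o]
        warnings.warn(f"landmarks outside the grid (edge-extrapolated): {bad}", stacklevel=2)
    disp = np.stack(
        [ndimage.map_coordinates(phi.u[c], vox.T, order=1, mode="nearest") for c in range(3)],
        axis=1,
    )
    new_vox = vox + disp
    return points.with_coordinates(new_vox * phi.spacing + phi.origin)


def invert(phi: DeformationField, tol: float = 0.01, max_iter: int = 50) -> DeformationField:
    """Invert a diffeomorphic field by fixed-point iteration.

    Iterates ``u⁻¹ ← −u(x + u⁻¹(x))`` until the largest update is below
    ``tol`` voxels. Non-convergence signals a non-diffeomorphic input and
    raises :class:`InversionError`.
    """
    grid = _grid_coords(phi.shape)
    u = phi.u.astype(np.float32)
    uinv = -u.copy()
    for _ in range(max_iter):
        coords = grid + uinv
        new = -_sample_vector(u, coords)
        delta = float(np.abs(new - uinv).max())
        uinv = new
        if delta < tol:
            return DeformationField(uinv, phi.spacing, phi.origin)
    raise InversionError(
        f"fixed-point inversion did not reach {tol} voxels in {max_iter} iterations "
        f"(last update {delta:.3g}); the field may not be diffeomorphic"
    )


# ---------------------------------------------------------------------------
# NIfTI I/O for vector fields and Jacobian maps


def _diag_affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_field(phi: DeformationField, path) -> None:
    """Write φ as a 4D NIfTI (nx, ny, nz, 3); displacement in voxel units of
    the fixed grid, noted in the header description."""
    import nibabel as nib

    img = nib.Nifti1Image(
        np.moveaxis(phi.u.astype(np.float32), 0, -1),
        _diag_affine(phi.spacing, phi.origin),
    )
    img.header["descrip"] = b"displacement u, voxel units, phi(x)=x+u(x)"
    nib.save(img, str(path))


def load_field(path) -> DeformationField:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx, ny, nz, 3) displacement volume")
    aff = img.affine
    return DeformationField(np.moveaxis(data, -1, 0), np.diag(aff[:3, :3]).copy(),
                            aff[:3, 3].copy())


def save_jacobian(J: JacobianMap, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(J.data.astype(np.float32), _diag_affine(J.spacing, J.origin))
    nib.save(img, str(path))
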