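"""12-parameter affine alignment of the second time point onto the first.

This is the linear initialization of the pipeline: the later scan is aligned
to the earlier one with a full affine (rotation, scale, shear, translation),
minimizing the sum of squared differences of the windowed intensities via a
multi-resolution regular-step gradient descent (SimpleITK registration
framework, full sampling — the optimization is deterministic).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "AffineTransform",
    "AffineRegistration",
    "AffineResults",
    "register_affine",
    "apply_affine",
]


@dataclasses.dataclass
class AffineTransform:
    """World-coordinate map y = A·x + t (fixed world mm → moving world mm)."""

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.isfinite(self.A).all() or not np.isfinite(self.t).all():
            raise ValueError("affine parameters must be finite")
        if np.linalg.det(self.A) <= 0:
            raise ValueError(f"affine must be orientation-preserving, det(A)={np.linalg.det(self.A):.4g}")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def __call__(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to world points of shape (..., 3)."""
        return np.asarray(xyz, dtype=float) @ self.A.T + self.t

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform(Ainv, -Ainv @ self.t)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.A
        m[:3, 3] = self.t
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.to_matrix().tolist()}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        with open(path) as fh:
            return cls.from_matrix(np.asarray(json.load(fh)["matrix"]))


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    # SimpleITK expects arrays ordered (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0), dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _world_bounds(vol: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    lo = vol.origin
    hi = vol.origin + (np.asarray(vol.shape) - 1) * vol.spacing
    return lo, hi


class AffineRegistration:
    """Model object for the affine stage; ``fit()`` runs the optimization.

    Parameters
    ----------
    fixed, moving : ImageVolume
        Windowed volumes on grids with identical spacing.
    levels : int
        Multi-resolution pyramid depth (shrink factors 2**(levels-1) … 1).
    iterations : int
        Optimizer iteration cap per level.
    """

    def __init__(self, fixed: ImageVolume, moving: ImageVolume, levels: int = 3,
                 iterations: int = 200):
        if not np.allclose(fixed.spacing, moving.spacing):
            raise ValueError("fixed and moving must share voxel spacing (resample first)")
        flo, fhi = _world_bounds(fixed)
        mlo, mhi = _world_bounds(moving)
        if np.any(fhi < mlo) or np.any(mhi < flo):
            raise ValueError("fields of view do not overlap; affine cost undefined")
        self.fixed = fixed
        self.moving = moving
        self.levels = int(levels)
        self.iterations = int(iterations)

    def fit(self) -> "AffineResults":
        f_img, m_img = _to_sitk(self.fixed), _to_sitk(self.moving)
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0,
            minStep=1e-6,
            numberOfIterations=self.iterations,
            relaxationFactor=0.6,
            gradientMagnitudeTolerance=1e-8,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        shrink = [2 ** (self.levels - 1 - i) for i in range(self.levels)]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([max(s // 2, 0) for s in shrink])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(initial, inPlace=True)
        final = reg.Execute(f_img, m_img)

        aff = sitk.AffineTransform(final if not isinstance(final, sitk.CompositeTransform)
                                   else final.GetNthTransform(0))
        A = np.asarray(aff.GetMatrix(), dtype=float).reshape(3, 3)
        c = np.asarray(aff.GetCenter(), dtype=float)
        t = np.asarray(aff.GetTranslation(), dtype=float)
        # sitk convention: y = A (x − c) + c + t
        transform = AffineTransform(A, c + t - A @ c)

        cost_identity = self._ssd(AffineTransform.identity())
        cost_final = self._ssd(transform)
        if cost_final > cost_identity:  # defensive: never return worse than identity
            transform, cost_final = AffineTransform.identity(), cost_identity
        return AffineResults(
            model=self,
            transform=transform,
            cost_identity=cost_identity,
            cost_final=cost_final,
            metric_value=float(reg.GetMetricValue()),
            stop_condition=reg.GetOptimizerStopConditionDescription(),
        )

    def _ssd(self, T: AffineTransform) -> float:
        warped = apply_affine(self.moving, T, self.fixed)
        return float(np.mean((warped.data - self.fixed.data) ** 2))


@dataclasses.dataclass
class AffineResults:
    """Fitted affine transform with cost diagnostics."""

    model: AffineRegistration
    transform: AffineTransform
    cost_identity: float
    cost_final: float
    metric_value: float
    stop_condition: str

    def apply(self, vol: ImageVolume, reference: ImageVolume | None = None) -> ImageVolume:
        return apply_affine(vol, self.transform, reference or self.model.fixed)

    def summary(self) -> str:
        m = self.to_matrix_string()
        return (
            "Affine registration (12-parameter, SSD, multi-resolution)\n"
            f"  mean squared difference at identity : {self.cost_identity:.6g}\n"
            f"  mean squared difference after fit   : {self.cost_final:.6g}\n"
            f"  det(A) = {np.linalg.det(self.transform.A):.5f}\n"
            f"  translation (mm) = {np.array2string(self.transform.t, precision=3)}\n"
            f"  stop: {self.stop_condition}\n"
            f"  matrix:\n{m}"
        )

    def to_matrix_string(self) -> str:
        return np.array2string(self.transform.to_matrix(), precision=5)


def register_affine(fixed: ImageVolume, moving: ImageVolume, *, levels: int = 3,
                    iterations: int = 200) -> AffineTransform:
    """Estimate the 12-parameter world-coordinate alignment moving→fixed frame."""
    return AffineRegistration(fixed, moving, levels=levels, iterations=iterations).fit().transform


def apply_affine(vol: ImageVolume, T: AffineTransform, reference: ImageVolume) -> ImageVolume:
    """Resample ``vol`` on the reference grid: out(x) = vol(A·x + t), trilinear."""
    if abs(np.linalg.det(T.A)) < 1e-12:
        raise ValueError("singular affine matrix")
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in reference.shape], indexing="ij"),
        axis=-1,
    )
    world = idx * reference.spacing + reference.origin
    mapped = T(world.reshape(-1, 3)).reshape(world.shape)
    vox = (mapped - vol.origin) / vol.spacing
    fill = float(vol.data.min())
    data = ndimage.map_coordinates(
        vol.data, np.moveaxis(vox, -1, 0), order=1, mode="constant", cval=fill
    )
    return ImageVolume(data, reference.spacing.copy(), reference.origin.copy())
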