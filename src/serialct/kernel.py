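"""Spectral smoothing kernel of the velocity-regularizing operator.

Velocities are regularized through L = −α∇² + γ·Id; gradients are smoothed
with K = (L†L)⁻¹, applied in Fourier space with periodic boundary and the
7-point discrete Laplacian symbol. α (smoothness) and γ (stability) are
dimensionless on the grid normalized to the unit cube: the Laplacian is
discretized with step 1/N per axis, so a given α/γ ratio selects a
comparable physical elasticity across grid sizes. A high α/γ ratio gives a
stiff, near-linear deformation; lowering the ratio admits increasingly
localized deformation — the basis of the cascading-elasticity schedule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import fft as sp_fft

__all__ = ["KernelParams", "SmoothingKernel", "apply_smoothing_kernel", "laplacian_eigenvalues"]


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Elasticity parameters of L = −α∇² + γ·Id.

    ``ratio`` = α/γ is the single number that controls elasticity; γ only
    rescales the kernel by 1/γ², which step-size normalization absorbs.
    """

    alpha: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError(f"alpha and gamma must be > 0, got α={self.alpha}, γ={self.gamma}")

    @property
    def ratio(self) -> float:
        return self.alpha / self.gamma

    @classmethod
    def from_ratio(cls, ratio: float, gamma: float = 1.0) -> "KernelParams":
        return cls(alpha=ratio * gamma, gamma=gamma)


def laplacian_eigenvalues(shape) -> np.ndarray:
    """Eigenvalues of −∇² (7-point stencil, periodic, unit-cube normalization).

    λ(k) = Σ_d (2 − 2 cos(2π k_d / N_d)) · N_d², broadcast over the rfft grid.
    """
    shape = tuple(int(n) for n in shape)
    lam = np.zeros((*shape[:-1], shape[-1] // 2 + 1))
    for d, n in enumerate(shape):
        k = np.fft.rfftfreq(n) * n if d == 2 else np.fft.fftfreq(n) * n
        lam_d = (2.0 - 2.0 * np.cos(2.0 * np.pi * k / n)) * n * n
        sl = [np.newaxis] * 3
        sl[d] = slice(None)
        lam = lam + lam_d[tuple(sl)]
    return lam


class SmoothingKernel:
    """K = (L†L)⁻¹ evaluated spectrally, with the symbol cached per grid shape."""

    def __init__(self, params: KernelParams, shape):
        self.params = params
        self.shape = tuple(int(n) for n in shape)
        lam = laplacian_eigenvalues(self.shape)
        self._khat = 1.0 / (params.alpha * lam + params.gamma) ** 2
        self._khat32 = self._khat.astype(np.float32)  # keeps float32 FFT pipelines single
        self._lhat2 = (params.alpha * lam + params.gamma) ** 2  # K⁻¹ symbol
        # K-preconditioned gradient of the curvature penalty mean‖α∇²u‖²:
        # 2(αλ)² / (αλ+γ)² — ≈2 at small scales, →0 for smooth fields
        self._penalty_sym = (2.0 * (params.alpha * lam) ** 2 * self._khat).astype(np.float32)

    def smooth(self, field: np.ndarray) -> np.ndarray:
        """Apply K componentwise to a (3, nx, ny, nz) or (nx, ny, nz) field."""
        field = np.asarray(field)
        if field.ndim == 3:
            return self._apply_one(field, self._khat)
        if field.ndim == 4 and field.shape[0] == 3 and field.shape[1:] == self.shape:
            return np.stack([self._apply_one(f, self._khat) for f in field])
        raise ValueError(f"field shape {field.shape} incompatible with grid {self.shape}")

    def sobolev_norm2(self, field: np.ndarray) -> float:
        """⟨K⁻¹ v, v⟩ = ‖Lv‖² per grid point — the velocity norm of the flow energy."""
        field = np.asarray(field, dtype=np.float64)
        comps = field if field.ndim == 4 else field[np.newaxis]
        total = 0.0
        n = np.prod(self.shape)
        for f in comps:
            fh = sp_fft.rfftn(f)
            # rfft stores half the spectrum: double the weight of non-self-conjugate bins
            w = np.full(fh.shape, 2.0)
            w[..., 0] = 1.0
            if self.shape[-1] % 2 == 0:
                w[..., -1] = 1.0
            total += float(np.sum(w * self._lhat2 * np.abs(fh) ** 2)) / n**2
        return total

    def penalty_gradient(self, field: np.ndarray) -> np.ndarray:
        """K-preconditioned gradient of the curvature energy mean‖α∇²u‖²,
        applied componentwise; used as the regularization part of the
        Sobolev descent direction."""
        field = np.asarray(field)
        if field.ndim == 3:
            return self._apply_one(field, self._penalty_sym)
        return np.stack([self._apply_one(c, self._penalty_sym) for c in field])

    def _apply_one(self, f: np.ndarray, symbol: np.ndarray) -> np.ndarray:
        if f.shape != self.shape:
            raise ValueError(f"field shape {f.shape} != grid {self.shape}")
        if symbol is self._khat and f.dtype == np.float32:
            symbol = self._khat32
        out = sp_fft.irfftn(sp_fft.rfftn(f) * symbol, s=self.shape)
        return out.astype(f.dtype, copy=False)


def apply_smoothing_kernel(field: np.ndarray, params: KernelParams) -> np.ndarray:
    """One-shot K·field for a (3, nx, ny, nz) or scalar (nx, ny, nz) field."""
    shape = field.shape[1:] if field.ndim == 4 else field.shape
    return SmoothingKernel(params, shape).smooth(field)
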