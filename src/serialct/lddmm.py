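"""Large Deformation Diffeomorphic Metric Mapping with cascading elasticity.

The registration estimates a smooth, invertible map φ (fixed/time-1 grid →
moving/time-2 coordinates) that warps the affinely aligned second time point
onto the first while provably retaining topology: every accepted iterate is
checked for strictly positive Jacobian determinant and the step is halved on
violation.

Two optimization modes are provided:

``greedy``
    Iterated composition of small kernel-smoothed diffeomorphisms
    (φ ← φ∘(id + εv), v = −K[(M∘φ − F)∇(M∘φ)]). One velocity update per
    iterate; the default operating mode.
``velocity``
    Time-discretized velocity field v_t (T steps, semi-Lagrangian flow
    integration) minimizing Σ_t‖v_t‖²_V·dt + ‖M∘φ − F‖²/σ² by Sobolev
    (kernel-smoothed) gradient descent. The flow of −v gives the inverse map.

Cascading elasticity runs consecutive registrations at strictly decreasing
α/γ ratios (default 0.01, 0.005, 0.002) on the re-warped image, composing
the per-stage maps: the stiff early stages remove bulk deformation, the
elastic late stages resolve localized change without topology violations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import DeformationField, compose, jacobian_determinant, warp_image
from .kernel import KernelParams, SmoothingKernel
from .volume import ImageVolume

__all__ = [
    "CascadeSchedule",
    "VelocityField",
    "DivergenceError",
    "LDDMM",
    "LDDMMResults",
    "CascadeLDDMM",
    "CascadeResults",
    "lddmm_register",
    "cascade_register",
]

DEFAULT_SCHEDULE = (0.01, 0.005, 0.002)


class DivergenceError(RuntimeError):
    """Optimization produced a non-finite cost; carries the iteration log."""

    def __init__(self, message: str, log: pd.DataFrame):
        super().__init__(message)
        self.log = log


@dataclasses.dataclass(frozen=True)
class CascadeSchedule:
    """Ordered α/γ ratios for cascading elasticity; strictly decreasing."""

    ratios: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        if not r:
            raise ValueError("cascade schedule must be non-empty")
        if any(x <= 0 for x in r):
            raise ValueError("ratios must be positive")
        if any(b >= a for a, b in zip(r, r[1:])):
            raise ValueError(f"ratios must be strictly decreasing, got {r}")
        object.__setattr__(self, "ratios", r)

    def __iter__(self):
        return iter(self.ratios)

    def __len__(self):
        return len(self.ratios)


@dataclasses.dataclass
class VelocityField:
    """Time-discretized velocity v_t (T steps × 3 components × grid), voxel units."""

    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v)
        if self.v.ndim != 5 or self.v.shape[1] != 3 or self.v.shape[0] < 1:
            raise ValueError(f"velocity must have shape (T, 3, nx, ny, nz), got {self.v.shape}")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity contains non-finite values")

    @property
    def timesteps(self) -> int:
        return self.v.shape[0]


# ---------------------------------------------------------------------------
# helpers on raw padded arrays (float32 throughout for speed)


def _grid(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    )


def _warp_scalar(img: np.ndarray, coords: np.ndarray, cval: float) -> np.ndarray:
    return ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=cval)


def _sample_u(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return np.stack(
        [ndimage.map_coordinates(u[c], coords, order=1, mode="nearest") for c in range(3)]
    )


def _operator_energy(u: np.ndarray, alpha: float, gamma: float) -> float:
    """mean ‖Lu‖² with L = −α∇² + γ·Id (7-point periodic Laplacian on the
    unit-cube-normalized grid) — the velocity norm of the flow energy."""
    total = 0.0
    shape = u.shape[1:]
    for c in range(3):
        uc = u[c]
        lap = np.zeros_like(uc, dtype=np.float32)
        for d in range(3):
            lap += (np.roll(uc, 1, axis=d) + np.roll(uc, -1, axis=d) - 2.0 * uc) \
                * np.float32(shape[d] ** 2)
        lu = np.float32(gamma) * uc - np.float32(alpha) * lap
        total += float(np.mean(lu.astype(np.float64) ** 2))
    return total


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Antialiased downsampling on the origin-aligned convention
    x_fine = factor * x_coarse (gaussian prefilter + strided sampling)."""
    sm = ndimage.gaussian_filter(img, 0.5 * factor)
    return np.ascontiguousarray(sm[::factor, ::factor, ::factor], dtype=np.float32)


def _resize_scalar(img: np.ndarray, target_shape) -> np.ndarray:
    """Origin-aligned linear resampling: out(x) = in(x * n_in/n_target)."""
    coords = _grid(target_shape)
    for d in range(3):
        coords[d] *= np.float32(img.shape[d] / target_shape[d])
    return ndimage.map_coordinates(img.astype(np.float32), coords, order=1,
                                   mode="nearest")


def _resize_field(u: np.ndarray, target_shape) -> np.ndarray:
    """Resample a displacement field onto a new grid (origin-aligned),
    rescaling the voxel-unit displacements by the per-axis grid ratio."""
    coords = _grid(target_shape)
    ratios = [t / s for t, s in zip(target_shape, u.shape[1:])]
    for d in range(3):
        coords[d] /= np.float32(ratios[d])
    out = np.empty((3, *target_shape), dtype=np.float32)
    for c in range(3):
        out[c] = ndimage.map_coordinates(u[c], coords, order=1, mode="nearest") \
            * np.float32(ratios[c])
    return out


def _relaxed_invert(u: np.ndarray, uinv: np.ndarray, tol: float = 0.005,
                    max_iter: int = 80, relax: float = 0.5) -> np.ndarray:
    """Under-relaxed polish of an approximate inverse displacement field;
    keeps the best iterate so the residual can only shrink."""
    grid = _grid(u.shape[1:])
    cur = uinv
    best, best_res = cur, np.inf
    for _ in range(max_iter):
        resid = cur + _sample_u(u, grid + cur)
        res = float(np.abs(resid).max())
        if res < best_res:
            best, best_res = cur, res
        if res < tol:
            break
        cur = cur - np.float32(relax) * resid
    return best


def _interior_jacobian_range(u: np.ndarray) -> tuple[float, float]:
    """(min, max) over interior voxels of det(I + Du), central differences.

    Slicing-based: evaluated on the interior only, avoiding np.gradient's
    per-axis allocations in the hot accept/reject loop.
    """
    g = np.empty((3, 3, *(n - 2 for n in u.shape[1:])), dtype=np.float32)
    for c in range(3):
        uc = u[c]
        g[c, 0] = (uc[2:, 1:-1, 1:-1] - uc[:-2, 1:-1, 1:-1]) * 0.5
        g[c, 1] = (uc[1:-1, 2:, 1:-1] - uc[1:-1, :-2, 1:-1]) * 0.5
        g[c, 2] = (uc[1:-1, 1:-1, 2:] - uc[1:-1, 1:-1, :-2]) * 0.5
        g[c, c] += 1.0
    det = (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )
    return float(det.min()), float(det.max())


# ---------------------------------------------------------------------------


class LDDMM:
    """Single-ratio diffeomorphic registration model.

    Parameters
    ----------
    fixed, moving : ImageVolume
        Volumes on the same grid (moving already affinely aligned),
        intensities in [0, 1].
    ratio : float
        α/γ elasticity ratio of the velocity-regularizing operator
        L = −α∇² + γ·Id (γ is fixed at 1, so α = ratio; the kernel depends
        only on the ratio up to a scale absorbed by step normalization).
    method : {"greedy", "velocity"}
    timesteps : int
        T for the velocity method (ignored by greedy).
    iterations : int
        Iteration cap (per registration).
    step_voxels : float
        Trial step: the largest per-iterate displacement update, in voxels.
    rtol : float
        Convergence when the relative cost decrease falls below this.
    pad : int
        Background guard band (voxels) against periodic FFT wrap-around.
    energy_weight : float
        Weight β of the deformation-energy term: the accepted objective is
        β·mean‖α∇²u‖² + SSD_matched/σ₀². The curvature energy is nearly zero
        for smooth bulk deformation but grows quadratically with localized
        small-scale displacement, so matching a residual must pay for the
        bending it spends; in particular, compressing an emerged nodule out
        of the warped image (or inflating a vanished one) is priced out,
        while tracking genuine smooth anatomy and sub-voxel nodule growth
        stays cheap. With β = 0 the optimizer will happily spend unbounded
        deformation on unpaired structure.
    jacobian_bounds : (float, float)
        Bounded elasticity: an iterate is accepted only while det(Dφ) of the
        stage map stays inside these bounds everywhere (the step is halved
        on violation). Tracking real serial anatomy needs modest local
        volume change; absorbing an emerged nodule (or conjuring a vanished
        one) requires extreme local compression/expansion, which the bound
        forbids.
    mask_unmatched : bool
        Cost-function masking of unmatched structure (standard practice when
        registering images containing pathology): bulky structure (voxels
        above ``structure_threshold`` surviving a 5-box erosion — nodules,
        not vessels) with no bulky partner within ``correspondence_radius``
        voxels in the other image is excluded from the matching term and
        advected with the ambient motion. A displaced or grown nodule finds
        its partner and is registered normally; an emerged or vanished
        nodule has no counterpart, is left untouched by the deformation
        (det(Dφ) ≈ 1 there — invisible on the Jacobian map) and therefore
        survives in the subtraction image.
    sigma2 : float, optional
        Data-noise scale of the matching term; default: the initial matched
        mean squared difference of this fit. The cascade pins later stages
        to the first stage's value.
    levels : int
        Multiresolution depth of the greedy optimizer (1 = single level).
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        ratio: float = 0.01,
        gamma: float = 1.0,
        method: str = "greedy",
        timesteps: int = 10,
        iterations: int = 100,
        step_voxels: float = 0.4,
        rtol: float = 1e-5,
        pad: int = 8,
        max_halvings: int = 8,
        energy_weight: float = 0.02,
        jacobian_bounds: tuple[float, float] = (0.5, 2.0),
        sigma2: float | None = None,
        mask_unmatched: bool = True,
        structure_threshold: float = 0.3,
        correspondence_radius: int = 8,
        levels: int = 1,
    ):
        if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
            raise ValueError("fixed and moving must be on the same grid")
        if method not in ("greedy", "velocity"):
            raise ValueError(f"unknown method {method!r}")
        self.fixed = fixed
        self.moving = moving
        self.params = KernelParams.from_ratio(ratio, gamma)
        self.method = method
        self.timesteps = int(timesteps)
        self.iterations = int(iterations)
        self.step_voxels = float(step_voxels)
        self.rtol = float(rtol)
        self.pad = int(pad)
        self.max_halvings = int(max_halvings)
        self.energy_weight = float(energy_weight)
        lo, hi = jacobian_bounds
        if not (0.0 <= lo < 1.0 < hi):
            raise ValueError(f"jacobian_bounds must bracket 1, got {jacobian_bounds}")
        self.jacobian_bounds = (float(lo), float(hi))
        self.sigma2 = sigma2  # data-noise scale; default: initial MSE of this fit
        self.mask_unmatched = bool(mask_unmatched)
        self.structure_threshold = float(structure_threshold)
        self.correspondence_radius = int(correspondence_radius)
        self.levels = int(levels)

    # -- public API ---------------------------------------------------------

    def fit(self) -> "LDDMMResults":
        if self.method == "greedy":
            return self._fit_greedy()
        return self._fit_velocity()

    # -- shared plumbing ----------------------------------------------------

    def _padded(self):
        p = self.pad
        f = np.pad(self.fixed.data.astype(np.float32), p, mode="constant",
                   constant_values=float(self.fixed.data.min()))
        m = np.pad(self.moving.data.astype(np.float32), p, mode="constant",
                   constant_values=float(self.moving.data.min()))
        return f, m

    def _crop(self, u: np.ndarray) -> np.ndarray:
        p = self.pad
        if p == 0:
            return u
        return u[:, p:-p, p:-p, p:-p].copy()

    def _field(self, u_padded: np.ndarray) -> DeformationField:
        return DeformationField(self._crop(u_padded), self.fixed.spacing.copy(),
                                self.fixed.origin.copy())

    def _results(self, u, uinv_padded, velocity, log, sigma2, converged):
        phi = self._field(u)
        phi_inv = self._field(uinv_padded)
        return LDDMMResults(
            model=self, phi=phi, phi_inv=phi_inv, velocity=velocity,
            log=self._log_frame(log), sigma2=sigma2, converged=converged,
        )

    # -- greedy mode --------------------------------------------------------

    def _fit_greedy(self) -> "LDDMMResults":
        """Coarse-to-fine greedy optimization.

        The smooth bulk of the deformation is solved on a 2x-downsampled
        level (where averaging halves the noise), then refined at full
        resolution from the upsampled warm start. The correspondence gate is
        computed once per fit from the input pair; its dilated margin covers
        structure motion up to the gate margin.
        """
        f0 = self.fixed.data.astype(np.float32)
        m0 = self.moving.data.astype(np.float32)
        levels = self.levels
        while levels > 1 and min(f0.shape) // 2 ** (levels - 1) < 24:
            levels -= 1
        gate0 = self._static_gate(f0, m0)

        u = uinv = None
        log = [(0, 1.0, float(np.mean((m0 - f0) ** 2)), 1.0, 0.0)]
        sigma2 = self.sigma2
        converged = False
        for lev in range(levels - 1, -1, -1):
            factor = 2 ** lev
            if factor > 1:
                f_l = _downsample(f0, factor)
                m_l = _downsample(m0, factor)
                gate_l = _resize_scalar(gate0, f_l.shape) if gate0 is not None else None
            else:
                f_l, m_l, gate_l = f0, m0, gate0
            if u is not None:
                u = _resize_field(u, f_l.shape)
                uinv = _resize_field(uinv, f_l.shape)
            u, uinv, log, sigma2_l, converged = self._greedy_level(
                f_l, m_l, gate_l, u, uinv,
                inpaint_radius=max(3, round(self.correspondence_radius / factor)))
            if lev == 0:
                sigma2 = sigma2_l
        phi = DeformationField(u, self.fixed.spacing.copy(), self.fixed.origin.copy())
        phi_inv = DeformationField(uinv, self.fixed.spacing.copy(),
                                   self.fixed.origin.copy())
        return LDDMMResults(
            model=self, phi=phi, phi_inv=phi_inv, velocity=None,
            log=self._log_frame(log), sigma2=float(sigma2), converged=converged,
        )

    def _static_gate(self, f: np.ndarray, m: np.ndarray) -> np.ndarray | None:
        """Cost-function mask: ~0 over bulky structure that has no bulky
        partner anywhere within the correspondence radius in the other
        image; 1 elsewhere.

        "Bulky" = voxels surviving a 5-box erosion of the structure mask:
        nodule-sized masses keep a core, vessels (thin tubes) and their
        junctions erode away entirely. A displaced or grown nodule finds its
        partner within the correspondence radius and is registered normally;
        an emerged or vanished one does not and is excluded from the
        matching term. The flagged cores are dilated back over the full mass
        plus a margin (so boundary forces are excluded and moderate motion
        stays covered) and smoothed.
        """
        if not self.mask_unmatched:
            return None
        core_size = 5
        size_c = 2 * self.correspondence_radius + 1
        core_f = ndimage.minimum_filter(f > self.structure_threshold, size=core_size)
        core_m = ndimage.minimum_filter(m > self.structure_threshold, size=core_size)
        cmax_f = ndimage.maximum_filter(core_f, size=size_c)
        cmax_m = ndimage.maximum_filter(core_m, size=size_c)
        unmatched = (core_m & ~cmax_f) | (core_f & ~cmax_m)
        if not unmatched.any():
            return None
        unmatched = ndimage.maximum_filter(unmatched, size=15)
        return ndimage.gaussian_filter(1.0 - unmatched.astype(np.float32), 2.0)

    def _greedy_level(self, f_full, m_full, gate_full, u0, uinv0,
                      inpaint_radius: int | None = None):
        """One pyramid level of greedy optimization on unpadded arrays."""
        if inpaint_radius is None:
            inpaint_radius = self.correspondence_radius
        p = self.pad
        f = np.pad(f_full, p, mode="constant", constant_values=float(f_full.min()))
        m = np.pad(m_full, p, mode="constant", constant_values=float(m_full.min()))
        gate = None
        if gate_full is not None:
            gate = np.pad(gate_full, p, mode="constant", constant_values=1.0)
        shape = f.shape
        grid = _grid(shape)
        kernel = SmoothingKernel(self.params, shape)
        mfill = float(m.min())
        alpha = self.params.alpha
        beta = self.energy_weight

        if u0 is None:
            u = np.zeros((3, *shape), dtype=np.float32)
            uinv = np.zeros_like(u)
        else:
            u = np.pad(u0, ((0, 0),) + ((p, p),) * 3)
            uinv = np.pad(uinv0, ((0, 0),) + ((p, p),) * 3)

        def matched_mse(warped: np.ndarray) -> float:
            r2 = (warped - f) ** 2
            if gate is not None:
                r2 = r2 * gate
            return float(np.mean(r2))

        sigma2 = max(matched_mse(m), 1e-12) if self.sigma2 is None \
            else float(self.sigma2)
        warped = _warp_scalar(m, grid + u, mfill) if u0 is not None else m.copy()
        ssd = float(np.mean((warped - f) ** 2))
        cost = beta * _operator_energy(u, alpha, 0.0) + matched_mse(warped) / sigma2
        log = [(0, cost, ssd, 1.0, 0.0)]
        converged = ssd <= 1e-12

        it = 0
        while not converged and it < self.iterations:
            it += 1
            if it > 1:
                warped = _warp_scalar(m, grid + u, mfill)
            resid = warped - f
            if gate is not None:
                resid = resid * gate
            gx, gy, gz = np.gradient(warped, edge_order=1)
            force = np.stack([resid * gx, resid * gy, resid * gz])
            v = -kernel.smooth(force / np.float32(sigma2))
            if beta > 0:
                # Sobolev descent of the full objective: the curvature
                # penalty contributes its preconditioned gradient to the
                # direction, so the accept test sees true descent directions
                v -= np.float32(beta) * kernel.penalty_gradient(u)
            if gate is not None:
                # advect the masked zone with the ambient motion: fill the
                # velocity inside the gate from its surroundings (normalized
                # convolution), so unmatched structure rides along instead
                # of lagging and shearing its neighbourhood
                den = ndimage.gaussian_filter(gate, inpaint_radius) + 1e-6
                for c in range(3):
                    filled = ndimage.gaussian_filter(
                        v[c] * gate, inpaint_radius) / den
                    v[c] = gate * v[c] + (1.0 - gate) * filled
            vmax = float(np.sqrt((v.astype(np.float64) ** 2).sum(axis=0)).max())
            if vmax < 1e-9:
                converged = True
                break
            v *= np.float32(self.step_voxels / vmax)

            accepted = False
            step = 1.0
            jlo, jhi = self.jacobian_bounds
            for _ in range(self.max_halvings + 1):
                sv = np.float32(step) * v
                u_new = sv + _sample_u(u, grid + sv)
                minj, maxj = _interior_jacobian_range(u_new)
                warped_new = _warp_scalar(m, grid + u_new, mfill)
                new_ssd = float(np.mean((warped_new - f) ** 2))
                # curvature energy (gamma = 0): smooth bulk displacement is
                # cheap, small-scale collapse/inflation is priced out
                new_cost = beta * _operator_energy(u_new, alpha, 0.0) \
                    + matched_mse(warped_new) / sigma2
                if not np.isfinite(new_cost):
                    raise DivergenceError(
                        "non-finite cost during greedy optimization",
                        self._log_frame(log),
                    )
                if minj > jlo and maxj < jhi and new_cost < cost:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                converged = True  # fixed point of the monotone scheme
                break
            # phi_new = phi o psi with psi = id + sv, so the inverse picks up
            # the small-step inverse psi^-1 ~ -sv o (id - sv) on the left:
            # uinv_new(y) = uinv(y) + u_psi_inv(y + uinv(y))
            w = -_sample_u(sv, grid - sv)
            uinv = uinv + _sample_u(w, grid + uinv)
            rel = (cost - new_cost) / max(abs(cost), 1e-30)
            u, cost, ssd = u_new, new_cost, new_ssd
            log.append((it, cost, ssd, minj, step * self.step_voxels))
            if rel < self.rtol:
                converged = True
                break

        uinv = self._refine_inverse(u, uinv, grid)
        crop = (slice(None),) + (slice(p, -p) if p else slice(None),) * 3
        return u[crop].copy(), uinv[crop].copy(), log, sigma2, converged

    @staticmethod
    def _log_frame(log) -> pd.DataFrame:
        return pd.DataFrame(log, columns=["iteration", "cost", "ssd", "min_jacobian", "step"])

    def _refine_inverse(self, u: np.ndarray, uinv: np.ndarray, grid: np.ndarray,
                        tol: float = 0.005, max_iter: int = 150,
                        relax: float = 0.5) -> np.ndarray:
        """Warm-started under-relaxed polish of the tracked inverse.

        Iterates uinv ← uinv − ω·(uinv + u∘(id + uinv)); the relaxation keeps
        the scheme contractive even where ‖Du‖ approaches 1 (where the plain
        fixed point stalls). The best iterate is kept, so accumulated
        tracking error can only shrink.
        """
        cur = uinv
        best, best_res = cur, np.inf
        for _ in range(max_iter):
            resid = cur + _sample_u(u, grid + cur)
            res = float(np.abs(resid).max())
            if res < best_res:
                best, best_res = cur, res
            if res < tol:
                break
            cur = cur - np.float32(relax) * resid
        return best

    # -- velocity (Beg-style) mode -----------------------------------------

    def _flow_maps(self, v: np.ndarray, grid: np.ndarray):
        """Semi-Lagrangian integration of the flow of v.

        Returns displacement series u_t0[t] for φ_{t,0} (time t → 0) and
        u_t1[t] for φ_{t,1} (time t → 1), t = 0 … T.
        """
        T = v.shape[0]
        dt = np.float32(1.0 / T)
        shape = v.shape[2:]
        u_t0 = [np.zeros((3, *shape), dtype=np.float32)]
        for t in range(1, T + 1):
            step = -dt * v[t - 1]
            u_t0.append(step + _sample_u(u_t0[-1], grid + step))
        u_t1 = [None] * (T + 1)
        u_t1[T] = np.zeros((3, *shape), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            step = dt * v[t]
            u_t1[t] = step + _sample_u(u_t1[t + 1], grid + step)
        return u_t0, u_t1

    def _energy(self, v, kernel, f, m, grid, mfill, sigma2):
        u_t0, u_t1 = self._flow_maps(v, grid)
        warped = _warp_scalar(m, grid + u_t0[-1], mfill)
        match = float(np.mean((warped - f) ** 2))
        reg = sum(kernel.sobolev_norm2(vt) for vt in v) / v.shape[0]
        return self.energy_weight * reg + match / sigma2, match, u_t0, u_t1

    def _fit_velocity(self) -> "LDDMMResults":
        f, m = self._padded()
        shape = f.shape
        grid = _grid(shape)
        kernel = SmoothingKernel(self.params, shape)
        mfill = float(m.min())
        T = self.timesteps
        dt = 1.0 / T

        v = np.zeros((T, 3, *shape), dtype=np.float32)
        sigma2 = max(float(np.mean((m - f) ** 2)), 1e-12) \
            if self.sigma2 is None else float(self.sigma2)
        energy, match, u_t0, u_t1 = self._energy(v, kernel, f, m, grid, mfill, sigma2)
        log = [(0, energy, match, 1.0, 0.0)]
        converged = match <= 1e-12

        it = 0
        while not converged and it < self.iterations:
            it += 1
            grad = np.empty_like(v)
            for t in range(T):
                j0 = _warp_scalar(m, grid + u_t0[t], mfill)
                j1 = _warp_scalar(f, grid + u_t1[t], float(f.min()))
                det = np.maximum(_det_field(u_t1[t]), 0.0)
                gx, gy, gz = np.gradient(j0, edge_order=1)
                w = (2.0 / sigma2) * det * (j0 - j1)
                body = np.stack([w * gx, w * gy, w * gz])
                grad[t] = 2.0 * v[t] - kernel.smooth(body)
            gmax = float(np.abs(grad).max())
            if gmax < 1e-9:
                converged = True
                break
            eps0 = self.step_voxels / (dt * gmax)

            accepted = False
            eps = eps0
            for _ in range(self.max_halvings + 1):
                v_new = v - np.float32(eps) * grad
                e_new, match_new, u_t0_new, u_t1_new = self._energy(
                    v_new, kernel, f, m, grid, mfill, sigma2
                )
                if not np.isfinite(e_new):
                    raise DivergenceError(
                        "non-finite energy during velocity optimization",
                        self._log_frame(log),
                    )
                minj, maxj = _interior_jacobian_range(u_t0_new[-1])
                if minj > self.jacobian_bounds[0] and maxj < self.jacobian_bounds[1] \
                        and e_new < energy:
                    accepted = True
                    break
                eps *= 0.5
            if not accepted:
                converged = True
                break
            rel = (energy - e_new) / max(abs(energy), 1e-30)
            v, energy, match = v_new, e_new, match_new
            u_t0, u_t1 = u_t0_new, u_t1_new
            log.append((it, energy, match, minj, eps))
            if rel < self.rtol:
                converged = True
                break

        p = self.pad
        vel = VelocityField(v[:, :, p:-p, p:-p, p:-p].copy() if p else v.copy())
        return self._results(u_t0[-1], u_t1[0], vel, log, sigma2, converged)


def _det_field(u: np.ndarray) -> np.ndarray:
    g = np.empty((3, 3, *u.shape[1:]), dtype=np.float32)
    for c in range(3):
        g[c, 0], g[c, 1], g[c, 2] = np.gradient(u[c], edge_order=1)
    for c in range(3):
        g[c, c] += 1.0
    return (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )


@dataclasses.dataclass
class LDDMMResults:
    """Fitted diffeomorphism with its inverse, velocity and iteration log."""

    model: LDDMM
    phi: DeformationField
    phi_inv: DeformationField
    velocity: VelocityField | None
    log: pd.DataFrame
    sigma2: float
    converged: bool

    @property
    def initial_cost(self) -> float:
        """Mean squared intensity difference before registration."""
        return float(self.log["ssd"].iloc[0])

    @property
    def final_cost(self) -> float:
        """Residual mean squared intensity difference (comparable across stages)."""
        return float(self.log["ssd"].iloc[-1])

    @property
    def min_jacobian(self) -> float:
        return jacobian_determinant(self.phi).min_interior()

    def jacobian(self):
        return jacobian_determinant(self.phi)

    def warp(self, vol: ImageVolume) -> ImageVolume:
        return warp_image(vol, self.phi)

    def summary(self) -> str:
        return (
            f"LDDMM registration ({self.model.method}, α/γ = {self.model.params.ratio:g})\n"
            f"  iterations          : {len(self.log) - 1}\n"
            f"  cost                : {self.initial_cost:.6g} → {self.final_cost:.6g}\n"
            f"  min det(Dφ)         : {self.min_jacobian:.4f}\n"
            f"  max |u| (voxels)    : {self.phi.max_displacement():.3f}\n"
            f"  converged           : {self.converged}"
        )


class CascadeLDDMM:
    """Cascading-elasticity registration: consecutive LDDMM runs at
    decreasing α/γ on the re-warped moving image, maps composed."""

    def __init__(self, fixed: ImageVolume, moving: ImageVolume,
                 schedule: CascadeSchedule | Sequence[float] = DEFAULT_SCHEDULE,
                 **lddmm_opts):
        if not isinstance(schedule, CascadeSchedule):
            schedule = CascadeSchedule(tuple(schedule))
        self.fixed = fixed
        self.moving = moving
        self.schedule = schedule
        self.lddmm_opts = lddmm_opts

    def fit(self) -> "CascadeResults":
        stages: list[LDDMMResults] = []
        phi_total: DeformationField | None = None
        inv_total: DeformationField | None = None
        sigma2 = self.lddmm_opts.pop("sigma2", None)
        for ratio in self.schedule:
            current = self.moving if phi_total is None else warp_image(self.moving, phi_total)
            res = LDDMM(self.fixed, current, ratio=ratio, sigma2=sigma2,
                        **self.lddmm_opts).fit()
            stages.append(res)
            if sigma2 is None:
                # the data-noise scale is a property of the image pair, not of
                # the stage: fix it at the first stage's initial mismatch so
                # later, more elastic stages cannot rationalize large
                # deformations against an ever-shrinking residual
                sigma2 = res.sigma2
            if phi_total is None:
                phi_total, inv_total = res.phi, res.phi_inv
            else:
                phi_total = compose(phi_total, res.phi)
                # (φ∘ψ)⁻¹ = ψ⁻¹∘φ⁻¹; stagewise inverses keep each fixed-point
                # problem well inside its contraction regime
                inv_total = compose(res.phi_inv, inv_total)
        # polish the composed inverse against the composed map: composition
        # interpolation error accumulates beyond the per-stage tolerance
        polished = _relaxed_invert(phi_total.u.astype(np.float32),
                                   inv_total.u.astype(np.float32))
        inv_total = DeformationField(polished, phi_total.spacing.copy(),
                                     phi_total.origin.copy())
        return CascadeResults(model=self, stages=stages, phi=phi_total, phi_inv=inv_total)


@dataclasses.dataclass
class CascadeResults:
    """Composed cascade map with per-stage diagnostics."""

    model: CascadeLDDMM
    stages: list[LDDMMResults]
    phi: DeformationField
    phi_inv: DeformationField

    @property
    def stage_costs(self) -> list[float]:
        """Residual mean squared difference at the end of each stage."""
        return [s.final_cost for s in self.stages]

    def jacobian(self):
        """det(Dφ) of the composed nonlinear map (the affine is excluded:
        it is estimated and applied upstream, so volume change here is
        purely the elastic deformation)."""
        return jacobian_determinant(self.phi)

    def warp(self, vol: ImageVolume) -> ImageVolume:
        return warp_image(vol, self.phi)

    def summary(self) -> str:
        lines = [
            f"Cascading-elasticity LDDMM, schedule {list(self.model.schedule.ratios)}"
        ]
        for ratio, s in zip(self.model.schedule, self.stages):
            lines.append(
                f"  stage α/γ={ratio:<7g} iters={len(s.log) - 1:<4d} "
                f"cost {s.initial_cost:.5g} → {s.final_cost:.5g}  minJ={s.min_jacobian:.3f}"
            )
        lines.append(f"  composed min det(Dφ) : {self.jacobian().min_interior():.4f}")
        lines.append(f"  composed max |u|     : {self.phi.max_displacement():.3f} voxels")
        return "\n".join(lines)


def lddmm_register(fixed: ImageVolume, moving: ImageVolume, ratio: float = 0.01,
                   **opts) -> tuple[VelocityField | None, DeformationField, DeformationField]:
    """Single-ratio LDDMM; returns (velocity, φ, φ⁻¹)."""
    res = LDDMM(fixed, moving, ratio=ratio, **opts).fit()
    return res.velocity, res.phi, res.phi_inv


def cascade_register(fixed: ImageVolume, moving: ImageVolume,
                     schedule: Sequence[float] = DEFAULT_SCHEDULE,
                     **opts) -> CascadeResults:
    """Cascading-elasticity registration; returns the composed results object."""
    return CascadeLDDMM(fixed, moving, schedule, **opts).fit()
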