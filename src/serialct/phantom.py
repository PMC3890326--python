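"""Synthetic serial lung-CT phantoms with analytic ground truth.

The generator emulates the structures the pipeline relies on in real chest
CT: dark parenchyma, bright branching vessel trees whose bifurcations serve
as unambiguous landmarks, and bright spherical nodules. A scripted temporal
change — a smooth global deformation composed with per-nodule radial
growth/shrinkage, plus painted-in (emerged) and removed (vanished) nodules —
produces the second time point together with the exact deformation field,
its analytic Jacobian determinant, truth landmark positions at both times,
and truth nodule masks. Everything is deterministic for a fixed seed.

Geometry is evaluated analytically at arbitrary continuous coordinates, so
the warped second time point and warped truth masks carry no resampling
blur beyond the numeric inversion of the truth map (tolerance 1e-3 voxel).

Intensities are in display-window units: background 0.05, vessels 0.9,
nodules 0.8, additive Gaussian noise (default sd 0.02).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fields import DeformationField, JacobianMap, invert
from .volume import BinaryMask, ImageVolume, Landmark, LandmarkSet

__all__ = [
    "VesselTreeSpec",
    "NoduleSpec",
    "PhantomSpec",
    "PhantomPair",
    "make_phantom_pair",
    "truth_jacobian",
]

CHANGE_KINDS = ("none", "grow", "shrink", "appear", "vanish")


@dataclasses.dataclass(frozen=True)
class VesselTreeSpec:
    """Branching-capsule vessel trees, one per lung."""

    trunks_per_lung: int = 3
    children_per_trunk: int = 3
    grandchildren_per_child: int = 2
    radii: tuple[float, float, float] = (2.2, 1.6, 1.1)  # voxels per level


@dataclasses.dataclass(frozen=True)
class NoduleSpec:
    """A spherical nodule and its scripted temporal change.

    ``factor`` is the volume ratio t2/t1 for grow/shrink (radius scales by
    factor**(1/3)); ignored for none/appear/vanish.
    """

    radius: float = 5.0
    intensity: float = 0.8
    change: str = "none"
    factor: float = 1.0
    center: tuple[float, float, float] | None = None  # voxel coords; auto-placed if None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nodule radius must be > 0")
        if self.change not in CHANGE_KINDS:
            raise ValueError(f"unknown change {self.change!r}; one of {CHANGE_KINDS}")
        if self.change in ("grow", "shrink") and self.factor <= 0:
            raise ValueError("grow/shrink factor must be > 0")

    @property
    def radial_scale(self) -> float:
        if self.change == "grow" or self.change == "shrink":
            return float(self.factor) ** (1.0 / 3.0)
        return 1.0


def default_nodules(per_class: int = 2, radius: float = 5.0,
                    grow: float = 1.3, shrink: float = 0.7) -> tuple[NoduleSpec, ...]:
    out = []
    for kind in CHANGE_KINDS:
        factor = {"grow": grow, "shrink": shrink}.get(kind, 1.0)
        out.extend(NoduleSpec(radius=radius, change=kind, factor=factor)
                   for _ in range(per_class))
    return tuple(out)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of a serial phantom pair."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0
    vessels: VesselTreeSpec = VesselTreeSpec()
    nodules: tuple[NoduleSpec, ...] = dataclasses.field(default_factory=default_nodules)
    warp_amplitude: float = 4.0  # max truth displacement, voxels
    warp_modes: int = 2  # low-frequency harmonics per displacement component
    noise_sd: float = 0.02
    background: float = 0.05
    texture_amplitude: float = 0.08  # faint parenchymal texture above background
    texture_modes: int = 6  # mid-frequency harmonics in the texture field
    vessel_intensity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if self.warp_amplitude < 0 or self.noise_sd < 0 or self.spacing <= 0:
            raise ValueError("invalid phantom parameters")


# ---------------------------------------------------------------------------
# analytic geometry


class _GlobalWarp:
    """Analytic smooth, near-volume-preserving displacement.

    u = ∇×A for a random low-frequency vector potential A (sums of separable
    first-harmonic sine products), scaled to a peak magnitude. Divergence-free
    u keeps the background Jacobian within a few percent of 1 — emulating
    breathing-matched serial CT, where parenchyma shifts but barely changes
    volume — so nodule growth/shrinkage is the dominant Jacobian signal.
    Displacement and gradient are evaluated in closed form at arbitrary
    points from the first and second partials of A.
    """

    def __init__(self, shape, amplitude: float, modes: int, rng: np.random.Generator):
        self.shape = np.asarray(shape, dtype=float)
        self.active = amplitude > 0
        self.coeff = rng.normal(size=(3, modes))
        self.phase = rng.uniform(0, 2 * np.pi, size=(3, modes, 3))
        if self.active:
            probe = self.displacement(_grid_points(shape))
            peak = float(np.sqrt((probe**2).sum(axis=0)).max())
            self.coeff *= amplitude / max(peak, 1e-12)
        else:
            self.coeff *= 0.0

    def _trig(self, pts: np.ndarray, i: int, m: int):
        w = 2.0 * np.pi / self.shape
        sins = [np.sin(w[d] * pts[d] + self.phase[i, m, d]) for d in range(3)]
        coss = [np.cos(w[d] * pts[d] + self.phase[i, m, d]) for d in range(3)]
        return sins, coss, w

    def _potential_d1(self, pts: np.ndarray, i: int, j: int) -> np.ndarray:
        """∂A_i/∂x_j at pts."""
        out = 0.0
        for m in range(self.coeff.shape[1]):
            sins, coss, w = self._trig(pts, i, m)
            term = self.coeff[i, m] * w[j] * coss[j]
            for d in range(3):
                if d != j:
                    term = term * sins[d]
            out = out + term
        return out

    def _potential_d2(self, pts: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
        """∂²A_i/∂x_j∂x_k at pts."""
        out = 0.0
        for m in range(self.coeff.shape[1]):
            sins, coss, w = self._trig(pts, i, m)
            if j == k:
                term = -self.coeff[i, m] * w[j] ** 2
                for d in range(3):
                    term = term * sins[d]
            else:
                term = self.coeff[i, m] * w[j] * w[k] * coss[j] * coss[k]
                for d in range(3):
                    if d != j and d != k:
                        term = term * sins[d]
            out = out + term
        return out

    # curl components: u_i = ∂A_c/∂x_b − ∂A_b/∂x_c for (i,b,c) cyclic
    _CURL = ((0, 1, 2), (1, 2, 0), (2, 0, 1))

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(pts, dtype=float)
        if not self.active:
            return out
        for i, b, c in self._CURL:
            out[i] = self._potential_d1(pts, c, b) - self._potential_d1(pts, b, c)
        return out

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        """Analytic ∂u_i/∂x_j at pts, shape (3, 3, ...); trace is zero."""
        g = np.zeros((3, 3, *pts.shape[1:]), dtype=float)
        if not self.active:
            return g
        for i, b, c in self._CURL:
            for j in range(3):
                g[i, j] = self._potential_d2(pts, c, b, j) - self._potential_d2(pts, b, c, j)
        return g


class _Texture:
    """Faint analytic parenchymal texture: a band of mid-frequency harmonics
    above the air background. Lung parenchyma is not featureless — vessels,
    septa and parenchymal density give intensity structure everywhere, which
    is what anchors an intensity-driven registration between the large
    vessels. Evaluated in closed form at arbitrary points, so it warps
    exactly with the truth map."""

    def __init__(self, shape, amplitude: float, modes: int, rng: np.random.Generator):
        self.shape = np.asarray(shape, dtype=float)
        self.amplitude = float(amplitude)
        self.coeff = rng.normal(size=modes)
        self.freq = rng.integers(2, 7, size=(modes, 3))
        self.phase = rng.uniform(0, 2 * np.pi, size=(modes, 3))
        if self.amplitude > 0:
            probe = self._raw(_grid_points(shape))
            self._norm = max(float(np.abs(probe).max()), 1e-9)
        else:
            self._norm = 1.0

    def _raw(self, pts: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi / self.shape
        out = 0.0
        for m in range(self.coeff.size):
            term = self.coeff[m]
            for d in range(3):
                term = term * np.sin(w[d] * self.freq[m, d] * pts[d] + self.phase[m, d])
            out = out + term
        return out

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        if self.amplitude == 0:
            return np.zeros(pts.shape[1:])
        field = self._raw(pts) / self._norm
        return self.amplitude * 0.5 * (1.0 + field)


def _grid_points(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )


def _radial_profile(rho: np.ndarray, r1: float, lam: float, r_out: float):
    """Displacement d(ρ) and derivative h'(ρ) of the radial map h = ρ + d.

    Inside ρ ≤ r1 the map is pure scaling by λ. The displacement then decays
    to zero by r_out along a C² quintic Hermite (value (λ−1)r1 and slope λ−1
    at r1; value, slope and curvature zero at r_out, curvature zero at r1),
    keeping h strictly monotone for the volume factors used here and smooth
    enough for accurate finite differencing of the truth field.
    """
    d = np.zeros_like(rho)
    hp = np.ones_like(rho)
    inside = rho <= r1
    d[inside] = (lam - 1.0) * rho[inside]
    hp[inside] = lam
    trans = (rho > r1) & (rho < r_out)
    delta = r_out - r1
    s = (rho[trans] - r1) / delta
    p0, m0 = (lam - 1.0) * r1, (lam - 1.0)
    h0 = 1 - 10 * s**3 + 15 * s**4 - 6 * s**5
    h1 = s - 6 * s**3 + 8 * s**4 - 3 * s**5
    d[trans] = h0 * p0 + h1 * delta * m0
    h0p = -30 * s**2 + 60 * s**3 - 30 * s**4
    h1p = 1 - 18 * s**2 + 32 * s**3 - 15 * s**4
    hp[trans] = 1.0 + h0p * p0 / delta + h1p * m0
    return d, hp


def _support_radius(r1: float) -> float:
    """Outer radius of a nodule's radial warp; displacement is zero beyond it.

    The transition width 1.2·r1 + 2 keeps the warp curvature low enough for
    central differences on the grid to track the analytic Jacobian to ~1%.
    """
    return 2.2 * float(r1) + 2.0


class _NoduleWarp:
    """Compactly supported radial growth/shrink field around one center."""

    def __init__(self, center: np.ndarray, r1: float, lam: float):
        self.center = np.asarray(center, dtype=float)
        self.r1 = float(r1)
        self.lam = float(lam)
        self.r_out = _support_radius(r1)

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - self.center.reshape(3, *([1] * (pts.ndim - 1)))
        rho = np.sqrt((rel**2).sum(axis=0))
        d, _ = _radial_profile(rho, self.r1, self.lam, self.r_out)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho > 1e-9, d / np.maximum(rho, 1e-9), self.lam - 1.0)
        return scale * rel

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - self.center.reshape(3, *([1] * (pts.ndim - 1)))
        rho = np.sqrt((rel**2).sum(axis=0))
        d, hp = _radial_profile(rho, self.r1, self.lam, self.r_out)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(rho > 1e-9, (rho + d) / np.maximum(rho, 1e-9), self.lam)
        return hp * ratio**2


@dataclasses.dataclass
class _Geometry:
    segments: list[tuple[np.ndarray, np.ndarray, float]]
    landmarks: list[Landmark]
    nodules: list[NoduleSpec]  # centers resolved
    global_warp: _GlobalWarp
    nodule_warps: list[_NoduleWarp]
    texture: "_Texture"


def _segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from (3, ...) points to the segment p0–p1."""
    d = p1 - p0
    L2 = float((d**2).sum())
    rel = pts - p0.reshape(3, *([1] * (pts.ndim - 1)))
    t = np.clip(np.tensordot(d, rel, axes=(0, 0)) / max(L2, 1e-12), 0.0, 1.0)
    proj = p0.reshape(3, *([1] * (pts.ndim - 1))) + t[None] * d.reshape(3, *([1] * (pts.ndim - 1)))
    return np.sqrt(((pts - proj) ** 2).sum(axis=0))


def _build_geometry(spec: PhantomSpec) -> _Geometry:
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    landmarks: list[Landmark] = []
    vt = spec.vessels
    margin = 10.0

    for side, x_frac in (("right", 0.30), ("left", 0.70)):
        for trunk_i in range(vt.trunks_per_lung):
            base = np.array([
                x_frac * nx + rng.uniform(-0.06, 0.06) * nx,
                (0.3 + 0.4 * trunk_i / max(vt.trunks_per_lung - 1, 1)) * ny
                + rng.uniform(-0.04, 0.04) * ny,
                0.18 * nz + rng.uniform(0, 0.05) * nz,
            ])
            tip = base + np.array([rng.uniform(-3, 3), rng.uniform(-3, 3), 0.28 * nz])
            tip = np.clip(tip, margin, np.array(spec.shape) - margin)
            segments.append((base, tip, vt.radii[0]))
            landmarks.append(Landmark(f"{side[0]}{trunk_i}_prox", side, "proximal",
                                      tuple(tip * spec.spacing)))
            for child_i in range(vt.children_per_trunk):
                ang = 2 * np.pi * (child_i + rng.uniform(0.1, 0.4)) / vt.children_per_trunk
                direction = np.array([np.cos(ang), np.sin(ang), rng.uniform(0.5, 1.0)])
                direction /= np.linalg.norm(direction)
                c_tip = np.clip(tip + direction * 0.16 * nz, margin,
                                np.array(spec.shape) - margin)
                segments.append((tip, c_tip, vt.radii[1]))
                landmarks.append(Landmark(f"{side[0]}{trunk_i}_{child_i}_dist", side,
                                          "distal", tuple(c_tip * spec.spacing)))
                for g_i in range(vt.grandchildren_per_child):
                    gang = ang + (g_i - 0.5) * rng.uniform(0.6, 1.2)
                    gdir = np.array([np.cos(gang), np.sin(gang), rng.uniform(0.3, 0.9)])
                    gdir /= np.linalg.norm(gdir)
                    g_tip = np.clip(c_tip + gdir * 0.10 * nz, margin,
                                    np.array(spec.shape) - margin)
                    segments.append((c_tip, g_tip, vt.radii[2]))

    # place nodules away from vessels and from each other; radial-warp
    # supports must stay pairwise disjoint (the analytic truth Jacobian
    # factorizes over nodules), plain nodules only need non-overlap
    nodules: list[NoduleSpec] = []
    occupied: list[tuple[np.ndarray, float, bool]] = []  # center, radius, has_warp

    def _clearance(r_a: float, warp_a: bool, r_b: float, warp_b: bool) -> float:
        if warp_a and warp_b:
            return _support_radius(r_a) + _support_radius(r_b) + 1.0
        if warp_a or warp_b:
            r_w, r_p = (r_a, r_b) if warp_a else (r_b, r_a)
            return _support_radius(r_w) + r_p + 2.0
        return r_a + r_b + 4.0

    for nod in spec.nodules:
        has_warp = nod.change in ("grow", "shrink")
        if nod.center is not None:
            center = np.asarray(nod.center, dtype=float)
        else:
            center = None
            pad = (_support_radius(nod.radius) if has_warp else nod.radius) + 2.0
            if any(4.0 + pad >= n - 4.0 - pad for n in spec.shape):
                raise ValueError(
                    f"grid {spec.shape} too small for a radius-{nod.radius} "
                    f"'{nod.change}' nodule (needs {2 * (4 + pad):.0f} voxels per axis)"
                )
            for attempt in range(6000):
                cand = rng.uniform(4.0 + pad, np.array(spec.shape, dtype=float) - 4.0 - pad)
                pt = cand.reshape(3, 1)
                dv = min(_segment_distance(pt, p0, p1)[0] - r for p0, p1, r in segments)
                dn_ok = all(
                    np.linalg.norm(cand - c) > _clearance(nod.radius, has_warp, rr, w)
                    for c, rr, w in occupied
                )
                vessel_slack = 1.0 - 0.6 * attempt / 6000.0
                if dv > (nod.radius + 4.0) * vessel_slack and dn_ok:
                    center = cand
                    break
            if center is None:
                raise ValueError("could not place all nodules; reduce count or radius")
        occupied.append((center, nod.radius, has_warp))
        nodules.append(dataclasses.replace(nod, center=tuple(center)))

    gw = _GlobalWarp(spec.shape, spec.warp_amplitude, spec.warp_modes, rng)
    tex = _Texture(spec.shape, spec.texture_amplitude, spec.texture_modes, rng)
    nws = [
        _NoduleWarp(np.asarray(n.center), n.radius, n.radial_scale)
        for n in nodules
        if n.change in ("grow", "shrink")
    ]
    return _Geometry(segments, landmarks, nodules, gw, nws, tex)


def _truth_displacement(geom: _Geometry, pts: np.ndarray) -> np.ndarray:
    """u of φ = φ_global ∘ φ_radial at arbitrary points (exact)."""
    ur = np.zeros_like(pts, dtype=float)
    for nw in geom.nodule_warps:
        ur += nw.displacement(pts)
    mid = pts + ur
    return ur + geom.global_warp.displacement(mid)


def _truth_jacobian_values(geom: _Geometry, pts: np.ndarray) -> np.ndarray:
    """det(Dφ) = det(Dφ_g at φ_r(x)) · J_radial(x); radial supports are disjoint."""
    jr = np.ones(pts.shape[1:], dtype=float)
    ur = np.zeros_like(pts, dtype=float)
    for nw in geom.nodule_warps:
        jr *= nw.jacobian(pts)
        ur += nw.displacement(pts)
    g = geom.global_warp.gradient(pts + ur)
    for i in range(3):
        g[i, i] += 1.0
    jg = (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )
    return jg * jr


def _render(geom: _Geometry, pts: np.ndarray, spec: PhantomSpec,
            include: set[str]) -> np.ndarray:
    """Analytic intensity at continuous voxel coordinates.

    ``include`` selects nodule change classes present in the rendered frame.
    Structure edges ramp linearly over one voxel (anti-aliased).
    """
    img = spec.background + geom.texture(pts)
    for p0, p1, r in geom.segments:
        d = _segment_distance(pts, p0, p1)
        ramp = np.clip(r + 0.5 - d, 0.0, 1.0)
        np.maximum(img, spec.background + (spec.vessel_intensity - spec.background) * ramp,
                   out=img)
    for nod in geom.nodules:
        if nod.change not in include:
            continue
        c = np.asarray(nod.center).reshape(3, *([1] * (pts.ndim - 1)))
        d = np.sqrt(((pts - c) ** 2).sum(axis=0))
        ramp = np.clip(nod.radius + 0.5 - d, 0.0, 1.0)
        np.maximum(img, spec.background + (nod.intensity - spec.background) * ramp, out=img)
    return img


def _sphere_mask(center, radius, pts) -> np.ndarray:
    c = np.asarray(center, dtype=float).reshape(3, *([1] * (pts.ndim - 1)))
    return ((pts - c) ** 2).sum(axis=0) <= radius**2


@dataclasses.dataclass
class PhantomPair:
    """A generated serial pair with full ground truth."""

    spec: PhantomSpec
    vol_t1: ImageVolume
    vol_t2: ImageVolume
    truth_phi: DeformationField  # t1 grid → t2 coordinates (exact on the grid)
    landmarks_t1: LandmarkSet
    landmarks_t2: LandmarkSet  # truth positions at time 2
    masks_t1: dict[int, BinaryMask]  # per nodule index (absent for 'appear')
    masks_t2: dict[int, BinaryMask]  # per nodule index (absent for 'vanish')
    regions: dict[int, BinaryMask]  # fixed-frame evaluation regions, all nodules
    labels: dict[int, str]  # nodule index → change class

    @property
    def truth_jacobian(self) -> JacobianMap:
        return truth_jacobian(self.spec)


def make_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate the serial pair, truth warp, landmarks, masks and labels."""
    geom = _build_geometry(spec)
    shape = spec.shape
    pts = _grid_points(shape)
    spacing = np.full(3, float(spec.spacing))
    origin = np.zeros(3)

    u = _truth_displacement(geom, pts)
    phi = DeformationField(u, spacing, origin)
    jmin = float(_truth_jacobian_values(geom, pts).min())
    if jmin <= 0.1:
        raise ValueError(
            f"truth warp min Jacobian {jmin:.3f} <= 0.1; lower warp_amplitude or factors"
        )

    rng = np.random.default_rng(spec.seed + 1_000_003)

    t1 = _render(geom, pts, spec, include={"none", "grow", "shrink", "vanish"})

    # second time point: pull the persistent scene back through φ⁻¹, then
    # paint emerged nodules at their time-2 locations
    if spec.warp_amplitude > 0 or geom.nodule_warps:
        psi = invert(phi, tol=1e-3, max_iter=100)
        back_pts = pts + psi.u
    else:
        back_pts = pts
    t2 = _render_warped(geom, back_pts, pts, spec)

    if spec.noise_sd > 0:
        t1 = np.clip(t1 + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, 1.0)
        t2 = np.clip(t2 + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, 1.0)

    vol_t1 = ImageVolume(t1, spacing, origin)
    vol_t2 = ImageVolume(t2, spacing, origin)

    lmk_t1 = LandmarkSet(geom.landmarks)
    vox1 = lmk_t1.coordinates() / spec.spacing
    vox2 = vox1 + _truth_displacement(geom, vox1.T).T
    lmk_t2 = lmk_t1.with_coordinates(vox2 * spec.spacing)

    masks_t1, masks_t2, regions, labels = {}, {}, {}, {}
    for idx, nod in enumerate(geom.nodules):
        labels[idx] = nod.change
        c = np.asarray(nod.center)
        if nod.change != "appear":
            masks_t1[idx] = BinaryMask(_sphere_mask(c, nod.radius, pts), spacing, origin)
        if nod.change != "vanish":
            r2 = nod.radius * nod.radial_scale
            if nod.change == "appear":
                masks_t2[idx] = BinaryMask(_sphere_mask(c, nod.radius, pts), spacing, origin)
            else:
                # time-2 footprint = φ(time-1 sphere): voxels whose pre-image
                # through φ⁻¹ lies inside the original radius
                masks_t2[idx] = BinaryMask(
                    _sphere_mask(c, nod.radius, back_pts), spacing, origin
                )
        if nod.change == "appear":
            # fixed-frame region: pre-image of the painted time-2 sphere
            fwd = pts + u
            regions[idx] = BinaryMask(_sphere_mask(c, nod.radius, fwd), spacing, origin)
        else:
            grown_r = nod.radius * max(nod.radial_scale, 1.0)
            regions[idx] = BinaryMask(_sphere_mask(c, grown_r, pts), spacing, origin)

    return PhantomPair(spec, vol_t1, vol_t2, phi, lmk_t1, lmk_t2,
                       masks_t1, masks_t2, regions, labels)


def _render_warped(geom: _Geometry, back_pts: np.ndarray, pts: np.ndarray,
                   spec: PhantomSpec) -> np.ndarray:
    t2 = _render(geom, back_pts, spec, include={"none", "grow", "shrink"})
    appear = _render(geom, pts, spec, include={"appear"})
    return np.maximum(t2, appear)


def truth_jacobian(spec: PhantomSpec) -> JacobianMap:
    """Analytic det(Dφ) of the truth warp on the grid (chain rule over the
    global and radial factors); min is guaranteed > 0.1 for accepted specs."""
    geom = _build_geometry(spec)
    pts = _grid_points(spec.shape)
    j = _truth_jacobian_values(geom, pts)
    if j.min() <= 0.1:
        raise ValueError("spec produces a near-singular truth warp")
    return JacobianMap(j, np.full(3, float(spec.spacing)), np.zeros(3))
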