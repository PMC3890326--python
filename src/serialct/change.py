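"""Reader-facing change outputs: temporal subtraction, color-coded Jacobian
maps, and change-pattern classification.

The two maps are complementary. A diffeomorphic registration can explain
growth/shrinkage of an existing nodule — the change then vanishes from the
subtraction image and shows up as det(Dφ) above/below 1 — but it cannot
create or delete structure: an emerged or vanished nodule is invisible on
the Jacobian map and survives in the subtraction image. The classifier
encodes exactly this signature table.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import JacobianMap
from .volume import BinaryMask, ImageVolume

__all__ = [
    "ChangeThresholds",
    "ChangePattern",
    "subtraction_image",
    "colorize_jacobian",
    "classify_change",
    "classify_regions",
    "propose_regions",
    "hybrid_overlay",
]


@dataclasses.dataclass(frozen=True)
class ChangeThresholds:
    """Decision cutoffs: τ_S on mean subtraction signal (windowed units),
    τ_J on deviation of mean Jacobian from 1."""

    tau_s: float = 0.1
    tau_j: float = 0.05


@dataclasses.dataclass(frozen=True)
class ChangePattern:
    """Per-region change call with its evidence.

    The Jacobian evidence is the region median normalized by the median
    over a surrounding background shell (``relative_jacobian``): the median
    is robust to small sub-volumes of extreme determinants, and the shell
    reference cancels whatever smooth volume change the ambient deformation
    carries through the neighbourhood, leaving the lesion's own growth
    signal.
    """

    label: str  # unchanged | growing | shrinking | emerged | vanished | ambiguous
    mean_subtraction: float
    median_jacobian: float
    reference_jacobian: float
    relative_jacobian: float
    n_voxels: int


def subtraction_image(fixed_t1: ImageVolume, registered_t2: ImageVolume) -> ImageVolume:
    """S = registered t2 − t1: zero where registered, positive (white) where
    tissue is new/denser at t2, negative (black) where it vanished."""
    if fixed_t1.shape != registered_t2.shape:
        raise ValueError("subtraction requires identical grids")
    return fixed_t1.like(registered_t2.data - fixed_t1.data)


def colorize_jacobian(J: JacobianMap, neutral_band: tuple[float, float] = (0.95, 1.05),
                      saturate: tuple[float, float] = (0.5, 2.0)
                      ) -> tuple[np.ndarray, int]:
    """Color-code det(Dφ): yellow inside the neutral band, ramping to red for
    growth (J→``saturate[1]``) and green for shrinkage (J→``saturate[0]``).

    Non-positive determinants (topology violations) are painted magenta and
    counted. Returns ``(rgb, n_nonpositive)`` with rgb in [0, 1],
    shape (*J.shape, 3); the mapping is monotone in J on each side.
    """
    lo, hi = neutral_band
    if not (0 < lo < 1 < hi):
        raise ValueError("neutral band must bracket 1")
    j = np.asarray(J.data, dtype=float)
    rgb = np.zeros((*j.shape, 3))
    rgb[..., 0] = 1.0  # start from yellow
    rgb[..., 1] = 1.0
    above = np.clip((j - hi) / (saturate[1] - hi), 0.0, 1.0)
    below = np.clip((lo - j) / (lo - saturate[0]), 0.0, 1.0)
    rgb[..., 1] -= above  # toward red
    rgb[..., 0] -= below  # toward green
    bad = j <= 0
    n_bad = int(bad.sum())
    if n_bad:
        rgb[bad] = (1.0, 0.0, 1.0)
    return rgb, n_bad


def classify_change(region: BinaryMask, S: ImageVolume, J: JacobianMap,
                    thresholds: ChangeThresholds = ChangeThresholds(),
                    shell: tuple[int, int] = (4, 10)) -> ChangePattern:
    """Call the change pattern of one region from (mean S, relative J).

    The Jacobian statistic is median(J in region) / median(J in a
    surrounding shell), the shell spanning dilations ``shell[0]``–``shell[1]``
    voxels of the region; if the shell is empty, the raw region median is
    used. The default shell starts beyond the correspondence-gate margin
    the registration places around unmatched structure, so the reference
    samples genuine ambient deformation.

    ==================  =========  ============
    pattern             mean S     relative J
    ==================  =========  ============
    unchanged           ≈ 0        ≈ 1
    growing             ≈ 0        > 1 + τ_J
    shrinking           ≈ 0        < 1 − τ_J
    emerged             ≫ 0        ≈ 1
    vanished            ≪ 0        ≈ 1
    ==================  =========  ============

    Combinations outside the table are labeled ``ambiguous`` with both
    scores reported.
    """
    m = region.data
    if not m.any():
        raise ValueError("empty region")
    if S.shape != m.shape or J.shape != m.shape:
        raise ValueError("region/S/J grids differ")
    ms = float(S.data[m].mean())
    mj = float(np.median(J.data[m]))
    inner = ndimage.binary_dilation(m, iterations=shell[0])
    outer = ndimage.binary_dilation(m, iterations=shell[1])
    ring = outer & ~inner
    ref = float(np.median(J.data[ring])) if ring.any() else 1.0
    rel = mj / ref if ref > 0 else mj
    ts, tj = thresholds.tau_s, thresholds.tau_j
    s_flat = abs(ms) <= ts
    j_flat = abs(rel - 1.0) <= tj
    if s_flat and j_flat:
        label = "unchanged"
    elif s_flat and rel > 1.0 + tj:
        label = "growing"
    elif s_flat and rel < 1.0 - tj:
        label = "shrinking"
    elif ms > ts and j_flat:
        label = "emerged"
    elif ms < -ts and j_flat:
        label = "vanished"
    else:
        label = "ambiguous"
    return ChangePattern(label, ms, mj, ref, rel, int(m.sum()))


def classify_regions(regions: Mapping, S: ImageVolume, J: JacobianMap,
                     thresholds: ChangeThresholds = ChangeThresholds()) -> pd.DataFrame:
    """Classify a mapping of region id → BinaryMask; one row per region."""
    rows = []
    for rid, mask in regions.items():
        p = classify_change(mask, S, J, thresholds)
        rows.append({"region": rid, "label": p.label, "mean_subtraction": p.mean_subtraction,
                     "median_jacobian": p.median_jacobian,
                     "reference_jacobian": p.reference_jacobian,
                     "relative_jacobian": p.relative_jacobian, "n_voxels": p.n_voxels})
    return pd.DataFrame(rows)


def propose_regions(S: ImageVolume, J: JacobianMap, s_cut: float = 0.2,
                    logj_cut: float = 0.1, min_voxels: int = 30) -> dict[int, BinaryMask]:
    """Candidate regions: connected components where |S| or |log J| is large.

    A screening aid only — callers with known lesions should supply masks.
    """
    exceed = (np.abs(S.data) > s_cut) | (np.abs(np.log(np.maximum(J.data, 1e-6))) > logj_cut)
    labeled, n = ndimage.label(exceed)
    out: dict[int, BinaryMask] = {}
    for i in range(1, n + 1):
        m = labeled == i
        if m.sum() >= min_voxels:
            out[len(out)] = BinaryMask(m, S.spacing, S.origin)
    return out


def hybrid_overlay(S: ImageVolume, J: JacobianMap,
                   neutral_band: tuple[float, float] = (0.95, 1.05),
                   alpha: float = 0.6) -> np.ndarray:
    """Grayscale subtraction with the color-coded Jacobian blended on top
    wherever J leaves the neutral band; one practical composite view."""
    gray = np.clip(0.5 + S.data / 2.0, 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    color, _ = colorize_jacobian(J, neutral_band)
    off_band = (J.data < neutral_band[0]) | (J.data > neutral_band[1])
    rgb[off_band] = (1 - alpha) * rgb[off_band] + alpha * color[off_band]
    return rgb
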