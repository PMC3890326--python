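"""End-to-end driver: preprocess → affine → (cascading) LDDMM →
subtraction / Jacobian / classification → volumetry → accuracy report.

The single entry point :func:`run_pipeline` consumes a plain config mapping
(the CLI builds it from YAML and flags) and writes an output bundle whose
layout mirrors the registration stages::

    outdir/
      manifest.json                 seed, parameters, package versions
      phantom/                      generated inputs (phantom runs only)
      affine/                       warped volume, subtraction, transform
      single_alpha/                 optional single-ratio LDDMM outputs
      cascade/                      per-stage subtractions + logs, composed
                                    field, Jacobian map + color/hybrid PNGs
      classification.csv            per-region change calls
      volumetry.csv                 v1/v2/percent change/Jacobian prediction
      accuracy.csv, anova.json      landmark accuracy (if landmarks known)

All CSV reports are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .affine import AffineRegistration
from .change import (ChangeThresholds, classify_regions, colorize_jacobian,
                     hybrid_overlay, propose_regions, subtraction_image)
from .evaluation import anova_posthoc, format_summary, landmark_displacement, summarize
from .fields import (compose, save_field, save_jacobian, warp_image,
                     warp_points)
from .lddmm import DEFAULT_SCHEDULE, LDDMM, CascadeLDDMM
from .phantom import NoduleSpec, PhantomSpec, make_phantom_pair
from .volume import (apply_window, load_landmarks, load_volume, resample_isotropic,
                     save_landmarks, save_mask, save_volume)
from .volumetry import jacobian_volume, percent_change, propagate_mask, volume_ml

__all__ = ["run_pipeline"]


def _save_png(path, array2d, cmap=None, vmin=None, vmax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.image as mimg

    mimg.imsave(str(path), np.rot90(array2d), cmap=cmap, vmin=vmin, vmax=vmax)


def _mid_axial(data: np.ndarray) -> np.ndarray:
    return data[:, :, data.shape[2] // 2]


def _lddmm_opts(config) -> dict:
    out = {}
    for key in ("method", "timesteps", "iterations", "step_voxels", "rtol", "pad",
                "energy_weight", "jacobian_bounds", "mask_unmatched",
                "structure_threshold", "correspondence_radius", "levels"):
        if key in config:
            out[key] = config[key]
    return out


def run_pipeline(config: dict) -> Path:
    """Run the full serial-change workflow; returns the output directory."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    schedule = tuple(config.get("schedule", DEFAULT_SCHEDULE))
    single_alpha = config.get("single_alpha")
    thresholds = ChangeThresholds(
        tau_s=float(config.get("tau_s", 0.1)), tau_j=float(config.get("tau_j", 0.05))
    )

    pair = None
    landmarks_t1 = landmarks_t2 = None
    if "phantom" in config:
        ph = dict(config["phantom"] or {})
        if "shape" in ph:
            ph["shape"] = tuple(int(n) for n in ph["shape"])
        if "nodules" in ph:
            ph["nodules"] = tuple(NoduleSpec(**n) for n in ph["nodules"])
        spec = PhantomSpec(seed=seed, **ph)
        pair = make_phantom_pair(spec)
        fixed, moving = pair.vol_t1, pair.vol_t2
        landmarks_t1, landmarks_t2 = pair.landmarks_t1, pair.landmarks_t2
        pdir = outdir / "phantom"
        pdir.mkdir(exist_ok=True)
        save_volume(fixed, pdir / "t1.nii.gz")
        save_volume(moving, pdir / "t2.nii.gz")
        save_landmarks(landmarks_t1, pdir / "landmarks_t1.csv")
        save_landmarks(landmarks_t2, pdir / "landmarks_t2.csv")
        save_field(pair.truth_phi, pdir / "truth_phi.nii.gz")
        with open(pdir / "truth_labels.json", "w") as fh:
            json.dump({str(k): v for k, v in pair.labels.items()}, fh, indent=2)
        run_affine = bool(config.get("run_affine", False))
    else:
        inputs = config["inputs"]
        fixed = load_volume(inputs["fixed"])
        moving = load_volume(inputs["moving"])
        if inputs.get("hounsfield", True):
            target = float(config.get("target_spacing", 1.0))
            level = float(config.get("window_level", -600.0))
            width = float(config.get("window_width", 600.0))
            fixed = apply_window(resample_isotropic(fixed, target), level, width)
            moving = apply_window(resample_isotropic(moving, target), level, width)
        if inputs.get("landmarks_t1"):
            landmarks_t1 = load_landmarks(inputs["landmarks_t1"])
        if inputs.get("landmarks_t2"):
            landmarks_t2 = load_landmarks(inputs["landmarks_t2"])
        run_affine = bool(config.get("run_affine", True))

    opts = _lddmm_opts(config)
    displacements: dict[str, pd.DataFrame] = {}
    affine_transform = None

    moving_aligned = moving
    if run_affine:
        adir = outdir / "affine"
        adir.mkdir(exist_ok=True)
        ares = AffineRegistration(fixed, moving).fit()
        affine_transform = ares.transform
        moving_aligned = ares.apply(moving)
        save_volume(moving_aligned, adir / "warped.nii.gz")
        sub_aff = subtraction_image(fixed, moving_aligned)
        save_volume(sub_aff, adir / "subtraction.nii.gz")
        _save_png(adir / "subtraction.png", _mid_axial(sub_aff.data),
                  cmap="gray", vmin=-0.5, vmax=0.5)
        ares.transform.save(adir / "transform.json")
    else:
        sub_aff = subtraction_image(fixed, moving_aligned)

    def transfer(phi):
        pts = warp_points(landmarks_t1, phi)
        if affine_transform is not None:
            pts = pts.with_coordinates(affine_transform(pts.coordinates()))
        return pts

    if landmarks_t1 is not None and landmarks_t2 is not None:
        base = landmarks_t1
        if affine_transform is not None:
            base = landmarks_t1.with_coordinates(affine_transform(landmarks_t1.coordinates()))
        displacements["affine"] = landmark_displacement(landmarks_t2, base)

    if single_alpha:
        sdir = outdir / "single_alpha"
        sdir.mkdir(exist_ok=True)
        sres = LDDMM(fixed, moving_aligned, ratio=float(single_alpha), **opts).fit()
        warped = sres.warp(moving_aligned)
        save_volume(warped, sdir / "warped.nii.gz")
        sub = subtraction_image(fixed, warped)
        save_volume(sub, sdir / "subtraction.nii.gz")
        _save_png(sdir / "subtraction.png", _mid_axial(sub.data),
                  cmap="gray", vmin=-0.5, vmax=0.5)
        save_field(sres.phi, sdir / "phi.nii.gz")
        sres.log.to_csv(sdir / "log.csv", index=False)
        if landmarks_t1 is not None and landmarks_t2 is not None:
            displacements["single_alpha"] = landmark_displacement(
                landmarks_t2, transfer(sres.phi))

    cdir = outdir / "cascade"
    cdir.mkdir(exist_ok=True)
    cres = CascadeLDDMM(fixed, moving_aligned, schedule, **opts).fit()
    composed = None
    for i, stage in enumerate(cres.stages, start=1):
        composed = stage.phi if composed is None else compose(composed, stage.phi)
        sub = subtraction_image(fixed, warp_image(moving_aligned, composed))
        save_volume(sub, cdir / f"subtraction_stage{i}.nii.gz")
        _save_png(cdir / f"subtraction_stage{i}.png", _mid_axial(sub.data),
                  cmap="gray", vmin=-0.5, vmax=0.5)
        stage.log.to_csv(cdir / f"stage{i}_log.csv", index=False)
    warped_final = cres.warp(moving_aligned)
    save_volume(warped_final, cdir / "warped.nii.gz")
    save_field(cres.phi, cdir / "phi.nii.gz")
    save_field(cres.phi_inv, cdir / "phi_inv.nii.gz")
    jac = cres.jacobian()
    save_jacobian(jac, cdir / "jacobian.nii.gz")
    sub_final = subtraction_image(fixed, warped_final)
    rgb, n_bad = colorize_jacobian(jac)
    mid = rgb.shape[2] // 2
    _save_png(cdir / "jacobian_color.png", rgb[:, :, mid, :])
    _save_png(cdir / "hybrid.png", hybrid_overlay(sub_final, jac)[:, :, mid, :])

    # change classification
    if pair is not None:
        regions = pair.regions
    else:
        regions = propose_regions(sub_final, jac)
    if regions:
        report = classify_regions(regions, sub_final, jac, thresholds)
        if pair is not None:
            report["truth"] = [pair.labels[r] for r in report["region"]]
        report.to_csv(outdir / "classification.csv", index=False)

    # volumetry through the inverse composed map
    vol_rows = []
    if pair is not None:
        for idx, mask in sorted(pair.masks_t1.items()):
            v1 = volume_ml(mask)
            m2 = propagate_mask(mask, cres.phi, cres.phi_inv)
            v2 = volume_ml(m2)
            vol_rows.append({
                "region": idx, "truth": pair.labels[idx],
                "v1_ml": v1, "v2_ml": v2,
                "percent_change": percent_change(v1, v2),
                "jacobian_predicted_ml": jacobian_volume(mask, jac),
            })
    elif config.get("volumetry_seeds"):
        from .volumetry import region_grow

        for i, seed_vox in enumerate(config["volumetry_seeds"]):
            mask = region_grow(fixed, tuple(seed_vox))
            save_mask(mask, outdir / f"nodule{i}_t1_mask.nii.gz")
            v1 = volume_ml(mask)
            m2 = propagate_mask(mask, cres.phi, cres.phi_inv)
            save_mask(m2, outdir / f"nodule{i}_t2_mask.nii.gz")
            v2 = volume_ml(m2)
            vol_rows.append({
                "region": i, "v1_ml": v1, "v2_ml": v2,
                "percent_change": percent_change(v1, v2),
                "jacobian_predicted_ml": jacobian_volume(mask, jac),
            })
    if vol_rows:
        pd.DataFrame(vol_rows).to_csv(outdir / "volumetry.csv", index=False)

    # landmark accuracy
    if landmarks_t1 is not None and landmarks_t2 is not None:
        displacements["cascade"] = landmark_displacement(landmarks_t2, transfer(cres.phi))
        table = summarize(displacements)
        # study-table layout: strata as rows, registration methods as columns
        format_summary(table, decimals=2).T.to_csv(outdir / "accuracy.csv")
        table.to_csv(outdir / "accuracy_full.csv")
        if len(displacements) >= 2:
            res = anova_posthoc(
                {k: v["distance_mm"].to_list() for k, v in displacements.items()})
            with open(outdir / "anova.json", "w") as fh:
                json.dump({
                    "F": res.f_statistic, "p": res.p_value,
                    "posthoc": res.method,
                    "pairwise": res.pairwise.to_dict(orient="records"),
                }, fh, indent=2)

    manifest = {
        "package": "serialct",
        "version": __version__,
        "seed": seed,
        "schedule": list(schedule),
        "single_alpha": single_alpha,
        "lddmm_options": opts,
        "run_affine": run_affine,
        "thresholds": dataclasses.asdict(thresholds),
        "stage_costs": cres.stage_costs,
        "min_jacobian": jac.min_interior(),
        "nonpositive_jacobian_voxels": n_bad,
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _versions() -> dict:
    import nibabel
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "nibabel": nibabel.__version__}
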