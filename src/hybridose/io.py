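"""File formats: NPZ planar studies, NIfTI SPECT volumes, CSV/YAML tables.

Planar studies round-trip through a single NPZ archive; SPECT studies are
written as NIfTI volumes (voxel size in the affine, mm) with a JSON sidecar
for times and calibration; TACs, TIA/TIAC and dose tables are plain CSV.
ROI pixel sets are stored as JSON lists of 0-based row-major indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .calibration import CameraConfig
from .kinetics import TimeActivityCurve
from .planar import PlanarFrame, PlanarStudy
from .spect import SpectStudy


def save_planar_study(study: PlanarStudy, path) -> None:
    arrays = {
        "times_h": study.times_h,
        "blank": study.blank,
        "transmission": study.transmission,
        "vial_roi": study.vial_roi,
        "dwell_s": np.array([f.dwell_s for f in study.frames]),
        "vial_activity_mbq": np.array(study.vial_activity_mbq),
        "pixel_mm": np.array(study.pixel_mm),
    }
    for i, f in enumerate(study.frames):
        arrays[f"ant_pk_{i}"] = f.anterior_pk
        arrays[f"ant_sc_{i}"] = f.anterior_sc
        arrays[f"post_pk_{i}"] = f.posterior_pk
        arrays[f"post_sc_{i}"] = f.posterior_sc
        arrays[f"vial_{i}"] = study.vial_images[i]
    np.savez_compressed(path, **arrays)


def load_planar_study(path, camera: CameraConfig | None = None) -> PlanarStudy:
    with np.load(path) as z:
        times = z["times_h"]
        frames = [
            PlanarFrame(
                anterior_pk=z[f"ant_pk_{i}"],
                anterior_sc=z[f"ant_sc_{i}"],
                posterior_pk=z[f"post_pk_{i}"],
                posterior_sc=z[f"post_sc_{i}"],
                dwell_s=float(z["dwell_s"][i]),
            )
            for i in range(times.size)
        ]
        return PlanarStudy(
            times_h=times,
            frames=frames,
            blank=z["blank"],
            transmission=z["transmission"],
            vial_images=[z[f"vial_{i}"] for i in range(times.size)],
            vial_roi=z["vial_roi"],
            vial_activity_mbq=float(z["vial_activity_mbq"]),
            camera=camera or CameraConfig(),
            pixel_mm=float(z["pixel_mm"]),
        )


def save_spect_study(study: SpectStudy, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    affine = np.diag([study.voxel_mm, study.voxel_mm, study.voxel_mm, 1.0])
    for i, vol in enumerate(study.volumes_cps):
        nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine), d / f"spect_{i}.nii")
    nib.save(
        nib.Nifti1Image(np.asarray(study.calibration_volume_cps, np.float32), affine),
        d / "calibration_cylinder.nii",
    )
    if study.labels is not None:
        nib.save(nib.Nifti1Image(np.asarray(study.labels, np.int16), affine), d / "labels.nii")
    meta = {
        "times_h": list(map(float, study.times_h)),
        "voxel_mm": study.voxel_mm,
        "calibration_activity_bq": study.calibration_activity_bq,
        "psf_sigma_mm": study.psf_sigma_mm,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_spect_study(directory, camera: CameraConfig | None = None) -> SpectStudy:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    times = np.asarray(meta["times_h"], float)
    volumes = [
        np.asarray(nib.load(d / f"spect_{i}.nii").dataobj, float) for i in range(times.size)
    ]
    labels_path = d / "labels.nii"
    labels = (
        np.asarray(nib.load(labels_path).dataobj, np.int16) if labels_path.exists() else None
    )
    return SpectStudy(
        times_h=times,
        volumes_cps=volumes,
        voxel_mm=float(meta["voxel_mm"]),
        calibration_volume_cps=np.asarray(
            nib.load(d / "calibration_cylinder.nii").dataobj, float
        ),
        calibration_activity_bq=float(meta["calibration_activity_bq"]),
        camera=camera or CameraConfig(),
        psf_sigma_mm=float(meta["psf_sigma_mm"]),
        labels=labels,
    )


def tacs_to_frame(tacs: dict[str, TimeActivityCurve]) -> pd.DataFrame:
    rows = [
        {"region": r, "method": t.method, "time_h": float(tt), "activity_mbq": float(a)}
        for r, t in tacs.items()
        for tt, a in zip(t.times_h, t.activities_mbq)
    ]
    return pd.DataFrame(rows)


def ground_truth_to_frame(gt) -> pd.DataFrame:
    """Analytic per-organ ground truth as a flat table (CSV-ready)."""
    return pd.DataFrame(
        {
            "region": list(gt.tia_mbq_h),
            "tia_mbq_h": [gt.tia_mbq_h[r] for r in gt.tia_mbq_h],
            "dose_gy": [gt.dose_gy[r] for r in gt.tia_mbq_h],
            "dose_gy_per_gbq": [gt.dose_gy_per_gbq[r] for r in gt.tia_mbq_h],
            "volume_ml": [gt.volume_ml[r] for r in gt.tia_mbq_h],
            "mass_g": [gt.mass_g[r] for r in gt.tia_mbq_h],
        }
    )


def save_roi_json(masks: dict[str, np.ndarray], path) -> None:
    """ROI pixel sets as 0-based row-major flat indices."""
    payload = {
        name: {"shape": list(mask.shape), "indices": np.flatnonzero(mask).tolist()}
        for name, mask in masks.items()
    }
    Path(path).write_text(json.dumps(payload))


def load_roi_json(path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, d in payload.items():
        mask = np.zeros(int(np.prod(d["shape"])), bool)
        mask[d["indices"]] = True
        out[name] = mask.reshape(d["shape"])
    return out
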