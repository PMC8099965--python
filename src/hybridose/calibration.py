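"""Count-to-activity calibration and recovery-coefficient correction.

Planar scintigraphy is calibrated against a vial of known activity imaged
during each whole-body scan (camera response in counts/MBq); SPECT is
calibrated against a large uniform water cylinder of known activity
(Bq per cps). Partial-volume losses of small objects in reconstructed SPECT
are corrected with volume-dependent recovery coefficients (RC), tabulated
from sphere-phantom measurements and interpolated log-linearly in volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .nuclide import LU177_LAMBDA_PHYS


@dataclass(frozen=True)
class CameraConfig:
    """Acquisition geometry and energy-window settings of the gamma camera.

    Energy windows follow the dual-energy-window (DEW) scatter-correction
    scheme: a 20% photopeak window at 208 keV and a 15% lower scatter window
    at 187 keV. Whole-body scan speed differs per time point (cm/min), which
    changes the effective per-pixel dwell time; the per-scan vial calibration
    absorbs this automatically.
    """

    photopeak_kev: float = 208.0
    photopeak_width_frac: float = 0.20
    scatter_kev: float = 187.0
    scatter_width_frac: float = 0.15
    planar_pixel_mm: float = 4.66
    spect_voxel_mm: float = 4.66
    scan_speed_cm_min: tuple[float, ...] = (15.0, 15.0, 12.0)
    planar_sensitivity_cps_per_mbq: float = 10.0
    spect_sensitivity_cps_per_mbq: float = 10.0
    spect_acq_time_s: float = 1500.0
    planar_psf_sigma_mm: float = 4.0
    scatter_fraction: float = 0.3
    scatter_psf_sigma_mm: float = 18.0
    blank_counts_per_pixel: float = 20000.0
    detector_axial_fov_cm: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.photopeak_width_frac < 1 and 0 < self.scatter_width_frac < 1):
            raise ValueError("energy-window width fractions must lie in (0, 1)")
        if self.planar_pixel_mm <= 0 or self.spect_voxel_mm <= 0:
            raise ValueError("pixel/voxel sizes must be positive")

    @property
    def photopeak_width_kev(self) -> float:
        return self.photopeak_kev * self.photopeak_width_frac

    @property
    def scatter_width_kev(self) -> float:
        return self.scatter_kev * self.scatter_width_frac

    @property
    def dew_ratio(self) -> float:
        """Photopeak-to-scatter window-width ratio used by DEW correction."""
        return self.photopeak_width_kev / self.scatter_width_kev

    def dwell_time_s(self, time_index: int) -> float:
        """Effective exposure of each pixel during a whole-body sweep, seconds.

        A point stays in the camera's axial field of view for
        (axial FOV)/(table speed); slower day-4 sweeps expose longer.
        """
        speed = self.scan_speed_cm_min[min(time_index, len(self.scan_speed_cm_min) - 1)]
        return self.detector_axial_fov_cm / speed * 60.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {"scan_speed_cm_min": list(self.scan_speed_cm_min)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "CameraConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["scan_speed_cm_min"] = tuple(d["scan_speed_cm_min"])
        return cls(**d)


@dataclass(frozen=True)
class RCTable:
    """Volume-dependent recovery coefficients, sorted by volume.

    ``plateau_volume_ml``: volumes at or above it take the plateau recovery
    (the recovery of the largest tabulated volume <= plateau, i.e. the last
    entry when the plateau equals the largest tabulated volume).
    """

    volumes_ml: tuple[float, ...]
    recoveries: tuple[float, ...]
    plateau_volume_ml: float

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ml, float)
        r = np.asarray(self.recoveries, float)
        if v.size == 0 or v.size != r.size:
            raise ValueError("RC table needs matching, non-empty volume/recovery lists")
        if np.any(np.diff(v) <= 0):
            raise ValueError("RC table volumes must be strictly increasing")
        if np.any(np.diff(r) < 0):
            raise ValueError("recovery must be non-decreasing with volume")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("recoveries must lie in (0, 1]")

    @property
    def plateau_recovery(self) -> float:
        v = np.asarray(self.volumes_ml)
        idx = np.searchsorted(v, self.plateau_volume_ml, side="right") - 1
        return self.recoveries[max(idx, 0)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "volumes_ml": list(self.volumes_ml),
                    "recoveries": list(self.recoveries),
                    "plateau_volume_ml": self.plateau_volume_ml,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "RCTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(tuple(d["volumes_ml"]), tuple(d["recoveries"]), d["plateau_volume_ml"])


def default_rc_table() -> RCTable:
    """Sphere-phantom recovery coefficients of the reference acquisition setup.

    0.85 for volumes >= 20 ml, falling to 0.79, 0.67 and 0.59 at sphere
    volumes of approximately 13, 10 and 6 ml.
    """
    return RCTable(
        volumes_ml=(6.0, 10.0, 13.0, 20.0),
        recoveries=(0.59, 0.67, 0.79, 0.85),
        plateau_volume_ml=20.0,
    )


def recovery_coefficient(volume_ml: float, table: RCTable) -> float:
    """Recovery coefficient for an object of the given volume.

    Exact at tabulated volumes, log-linear interpolation in volume between
    neighbours, plateau recovery at/above the plateau volume, and clamped
    (with a warning) below the smallest tabulated volume.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    v = np.asarray(table.volumes_ml, float)
    r = np.asarray(table.recoveries, float)
    if volume_ml >= table.plateau_volume_ml:
        return float(table.plateau_recovery)
    if volume_ml < v[0]:
        warnings.warn(
            f"volume {volume_ml:.2f} ml below smallest tabulated RC volume "
            f"({v[0]:.2f} ml); clamping to RC={r[0]:.2f}",
            stacklevel=2,
        )
        return float(r[0])
    return float(np.interp(np.log(volume_ml), np.log(v), r))


@dataclass(frozen=True)
class CalibrationFactors:
    planar_cf_counts_per_mbq: float
    spect_cf_bq_per_cps: float

    def __post_init__(self) -> None:
        if self.planar_cf_counts_per_mbq <= 0 or self.spect_cf_bq_per_cps <= 0:
            raise ValueError("calibration factors must be positive")


def planar_calibration_factor(
    image: np.ndarray,
    vial_roi: np.ndarray,
    vial_activity_mbq: float,
    *,
    decay_time_h: float = 0.0,
    lambda_phys: float = LU177_LAMBDA_PHYS,
) -> float:
    """Camera response in counts/MBq from a vial of known activity.

    ``vial_activity_mbq`` is the assayed activity; it is decay-corrected with
    the physical decay constant over ``decay_time_h`` (assay to scan start)
    before division, so the factor refers to the activity actually present.
    """
    if vial_activity_mbq <= 0:
        raise ValueError("vial activity must be positive")
    roi = np.asarray(vial_roi, bool)
    if not roi.any():
        raise ValueError("vial ROI is empty")
    counts = float(np.asarray(image)[roi].sum())
    if counts <= 0:
        raise ValueError("zero counts in vial ROI: acquisition failure")
    activity_at_scan = vial_activity_mbq * np.exp(-lambda_phys * decay_time_h)
    return counts / activity_at_scan


def spect_calibration_factor(
    volume_cps: np.ndarray,
    phantom_activity_bq: float,
    voi: np.ndarray | None = None,
) -> float:
    """SPECT calibration factor in Bq per cps from a uniform cylinder scan."""
    if phantom_activity_bq <= 0:
        raise ValueError("phantom activity must be positive")
    vol = np.asarray(volume_cps, float)
    if voi is not None:
        voi = np.asarray(voi, bool)
        if not voi.any():
            raise ValueError("empty calibration VOI")
        total_cps = float(vol[voi].sum())
    else:
        total_cps = float(vol.sum())
    if total_cps <= 0:
        raise ValueError("no counts in calibration VOI")
    return phantom_activity_bq / total_cps


def rescale_rc_table(table: RCTable, factor: float) -> RCTable:
    """Return a copy of ``table`` with recoveries multiplied by ``factor``."""
    r = tuple(min(x * factor, 1.0) for x in table.recoveries)
    return replace(table, recoveries=r)
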