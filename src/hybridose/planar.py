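"""Conjugate-view planar activity quantification (the "2D method").

Activity in a source region is estimated from opposed anterior/posterior
whole-body images as

    A = sqrt(C_A * C_P / T) * f / cf

where ``C_A``, ``C_P`` are scatter- and background-corrected counts in the
organ ROI, ``T`` the transmission factor through the body at the organ
(from a blank and a patient transmission scan), ``f`` the source
self-attenuation correction for an extended source of thickness ``t``
(``f = (mu*t/2)/sinh(mu*t/2)``), and ``cf`` the camera response in
counts/MBq from the per-scan vial calibration. Organs partially hidden by
overlapping high-uptake tissue are quantified on their visible part and
extrapolated assuming homogeneous uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .calibration import CameraConfig, planar_calibration_factor
from .kinetics import TimeActivityCurve
from .nuclide import LU177_LAMBDA_PHYS


@dataclass
class PlanarFrame:
    """One whole-body acquisition: A/P photopeak and scatter-window grids."""

    anterior_pk: np.ndarray
    anterior_sc: np.ndarray
    posterior_pk: np.ndarray
    posterior_sc: np.ndarray
    dwell_s: float


@dataclass
class PlanarStudy:
    """Serial planar study plus blank/transmission scans and vial calibration."""

    times_h: np.ndarray
    frames: list[PlanarFrame]
    blank: np.ndarray
    transmission: np.ndarray
    vial_images: list[np.ndarray]
    vial_roi: np.ndarray
    vial_activity_mbq: float  # assayed at t = 0 (injection time)
    camera: CameraConfig
    pixel_mm: float
    true_shifts: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_times(self) -> int:
        return len(self.frames)


@dataclass
class RoiPair:
    """Pixel sets for one source region: boundary, background, visibility.

    ``visible_fraction`` is the fraction of the organ not hidden by
    overlapping tissue (projected-area ratio from the CT/label contours).
    """

    boundary: np.ndarray
    background: np.ndarray
    visible_fraction: float = 1.0
    organ_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary, bool)
        g = np.asarray(self.background, bool)
        if not b.any():
            raise ValueError("boundary ROI is empty")
        if not g.any():
            raise ValueError("background ROI is empty")
        if (b & g).any():
            raise ValueError("background ROI must not intersect the boundary ROI")
        if not (0 < self.visible_fraction <= 1):
            raise ValueError("visible_fraction must lie in (0, 1]")


@dataclass
class TransmissionMap:
    """Per-pixel transmission factor T = I_trans / I_blank and body thickness."""

    t_factor: np.ndarray
    thickness_cm: np.ndarray
    mu_per_cm: float

    @classmethod
    def from_blank_transmission(
        cls, blank: np.ndarray, transmission: np.ndarray, mu_per_cm: float
    ) -> "TransmissionMap":
        blank = np.asarray(blank, float)
        trans = np.asarray(transmission, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(blank > 0, trans / blank, 1.0)
        t = np.clip(t, 1e-9, 1.0)
        thickness = -np.log(t) / mu_per_cm
        return cls(t_factor=t, thickness_cm=thickness, mu_per_cm=mu_per_cm)


def coregister_planar(study: PlanarStudy) -> tuple[PlanarStudy, list[tuple[int, int]]]:
    """Rigid 2-D translation alignment of serial frames to the first frame.

    Integer-pixel shifts are estimated by count cross-correlation on the
    summed A/P photopeak images and undone with a periodic shift (frames are
    simulated/stored with empty margins, so wrap-around is benign). A shift
    at the edge of the correlation search window triggers a warning.
    """
    if study.n_times < 2:
        raise ValueError("co-registration needs at least two time points")
    ref = study.frames[0].anterior_pk + study.frames[0].posterior_pk
    shifts: list[tuple[int, int]] = [(0, 0)]
    frames = [study.frames[0]]
    max_shift = np.array(ref.shape) // 2
    for fr in study.frames[1:]:
        moving = fr.anterior_pk + fr.posterior_pk
        shift, _, _ = phase_cross_correlation(ref, moving, upsample_factor=1, normalization=None)
        dr, dc = int(round(shift[0])), int(round(shift[1]))
        if abs(dr) >= max_shift[0] - 1 or abs(dc) >= max_shift[1] - 1:
            warnings.warn(
                f"registration shift ({dr}, {dc}) at search-window edge: possible failure",
                stacklevel=2,
            )
        frames.append(
            PlanarFrame(
                anterior_pk=np.roll(fr.anterior_pk, (dr, dc), axis=(0, 1)),
                anterior_sc=np.roll(fr.anterior_sc, (dr, dc), axis=(0, 1)),
                posterior_pk=np.roll(fr.posterior_pk, (dr, dc), axis=(0, 1)),
                posterior_sc=np.roll(fr.posterior_sc, (dr, dc), axis=(0, 1)),
                dwell_s=fr.dwell_s,
            )
        )
        shifts.append((dr, dc))
    aligned = PlanarStudy(
        times_h=study.times_h,
        frames=frames,
        blank=study.blank,
        transmission=study.transmission,
        vial_images=study.vial_images,
        vial_roi=study.vial_roi,
        vial_activity_mbq=study.vial_activity_mbq,
        camera=study.camera,
        pixel_mm=study.pixel_mm,
        true_shifts=study.true_shifts,
    )
    return aligned, shifts


def scatter_correct(
    photopeak: np.ndarray, scatter: np.ndarray, w_pk_kev: float, w_sc_kev: float
) -> np.ndarray:
    """Dual-energy-window scatter correction, floored at zero pixelwise.

    C_primary = C_pk - C_sc * (W_pk / W_sc)
    """
    if w_pk_kev <= 0 or w_sc_kev <= 0:
        raise ValueError("window widths must be positive")
    pk = np.asarray(photopeak, float)
    sc = np.asarray(scatter, float)
    if (pk < 0).any() or (sc < 0).any():
        raise ValueError("count grids must be non-negative")
    return np.clip(pk - sc * (w_pk_kev / w_sc_kev), 0.0, None)


def threshold_segment(
    anterior: np.ndarray,
    posterior: np.ndarray,
    boundary: np.ndarray,
    fraction: float = 0.4,
) -> np.ndarray:
    """Threshold segmentation of the organ inside a boundary ROI.

    Uses the geometric mean of the anterior and posterior images so both
    views contribute; keeps pixels >= ``fraction`` of the in-boundary
    maximum.
    """
    if not (0 < fraction < 1):
        raise ValueError("threshold fraction must lie in (0, 1)")
    boundary = np.asarray(boundary, bool)
    if not boundary.any():
        raise ValueError("boundary ROI is empty")
    gm = np.sqrt(np.clip(anterior, 0, None) * np.clip(posterior, 0, None))
    peak = gm[boundary].max()
    if peak <= 0:
        raise ValueError("no counts inside the boundary ROI")
    mask = boundary & (gm >= fraction * peak)
    if not mask.any():
        raise ValueError("threshold segmentation produced an empty mask")
    return mask


def background_correct(
    organ_counts: float, background_counts: float, n_bg_pixels: int, n_organ_pixels: int
) -> float:
    """Subtract background counts per pixel scaled to the organ ROI size."""
    if n_bg_pixels <= 0:
        raise ValueError("background ROI must contain pixels")
    corrected = organ_counts - (background_counts / n_bg_pixels) * n_organ_pixels
    return max(corrected, 0.0)


def self_attenuation_factor(mu_per_cm: float, thickness_cm: float) -> float:
    """Extended-source correction f = (mu*t/2)/sinh(mu*t/2); -> 1 as t -> 0."""
    x = 0.5 * mu_per_cm * thickness_cm
    if x < 1e-8:
        return 1.0
    return x / np.sinh(x)


def conjugate_view_activity(
    anterior_counts,
    posterior_counts,
    tmap: TransmissionMap,
    organ_mask: np.ndarray,
    organ_thickness_cm: float,
    mu_per_cm: float,
    cf_counts_per_mbq: float,
    *,
    per_pixel: bool = False,
) -> float:
    """Conjugate-view (geometric-mean) activity estimate in MBq.

    By default the ROI-mean transmission factor is used with the summed
    A/P counts; ``per_pixel=True`` instead applies the geometric mean
    pixelwise with the per-pixel transmission before summing.
    """
    if cf_counts_per_mbq <= 0:
        raise ValueError("calibration factor must be positive")
    mask = np.asarray(organ_mask, bool)
    f = self_attenuation_factor(mu_per_cm, organ_thickness_cm)
    if per_pixel:
        a = np.clip(np.asarray(anterior_counts, float)[mask], 0, None)
        p = np.clip(np.asarray(posterior_counts, float)[mask], 0, None)
        t = tmap.t_factor[mask]
        if np.any(t <= 0):
            raise ValueError("non-positive transmission factor in organ ROI")
        return float(np.sum(np.sqrt(a * p / t)) * f / cf_counts_per_mbq)
    t_mean = float(tmap.t_factor[mask].mean())
    if t_mean <= 0:
        raise ValueError("non-positive mean transmission factor in organ ROI")
    c_a = float(np.sum(anterior_counts)) if np.ndim(anterior_counts) else float(anterior_counts)
    c_p = float(np.sum(posterior_counts)) if np.ndim(posterior_counts) else float(posterior_counts)
    return float(np.sqrt(c_a * c_p / t_mean) * f / cf_counts_per_mbq)


def partial_organ_extrapolate(counts_visible: float, visible_fraction: float) -> float:
    """Extrapolate counts of the visible organ part to the whole organ."""
    if not (0 < visible_fraction <= 1):
        raise ValueError("visible fraction must lie in (0, 1]")
    return counts_visible / visible_fraction


def quantify_planar_study(
    study: PlanarStudy,
    rois: dict[str, RoiPair],
    organ_thickness_cm: dict[str, float],
    *,
    mu_per_cm: float = 0.11,
    threshold_fraction: float = 0.4,
    per_pixel_attenuation: bool = False,
    register: bool = True,
    lambda_phys: float = LU177_LAMBDA_PHYS,
) -> dict[str, TimeActivityCurve]:
    """Full 2D chain: registration, scatter, segmentation, background,
    conjugate view, partial-organ extrapolation; one TAC per region."""
    if register and study.n_times >= 2:
        study, _ = coregister_planar(study)
    tmap = TransmissionMap.from_blank_transmission(study.blank, study.transmission, mu_per_cm)
    w_pk = study.camera.photopeak_width_kev
    w_sc = study.camera.scatter_width_kev

    tacs: dict[str, TimeActivityCurve] = {}
    for region, roi in rois.items():
        activities = np.zeros(study.n_times)
        for i, frame in enumerate(study.frames):
            cf = planar_calibration_factor(
                study.vial_images[i],
                study.vial_roi,
                study.vial_activity_mbq,
                decay_time_h=float(study.times_h[i]),
                lambda_phys=lambda_phys,
            )
            ant = scatter_correct(frame.anterior_pk, frame.anterior_sc, w_pk, w_sc)
            post = scatter_correct(frame.posterior_pk, frame.posterior_sc, w_pk, w_sc)
            mask = threshold_segment(ant, post, roi.boundary, threshold_fraction)
            n_bg = int(roi.background.sum())
            if per_pixel_attenuation:
                bg_a = float(ant[roi.background].sum()) / n_bg
                bg_p = float(post[roi.background].sum()) / n_bg
                c_a = np.clip(ant - bg_a, 0.0, None)
                c_p = np.clip(post - bg_p, 0.0, None)
            else:
                c_a = background_correct(
                    float(ant[mask].sum()), float(ant[roi.background].sum()), n_bg, int(mask.sum())
                )
                c_p = background_correct(
                    float(post[mask].sum()), float(post[roi.background].sum()), n_bg, int(mask.sum())
                )
            a_visible = conjugate_view_activity(
                c_a,
                c_p,
                tmap,
                mask,
                organ_thickness_cm[region],
                mu_per_cm,
                cf,
                per_pixel=per_pixel_attenuation,
            )
            activities[i] = partial_organ_extrapolate(a_visible, roi.visible_fraction)
        weights = 1.0 / np.maximum(activities, 1e-6)
        tacs[region] = TimeActivityCurve(
            times_h=np.asarray(study.times_h, float),
            activities_mbq=activities,
            weights=weights,
            method="2D",
            region=region,
        )
    return tacs
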