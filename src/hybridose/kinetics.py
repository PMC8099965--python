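"""Time-activity curves, mono-exponential fits, time-integrated activity.

The time-integrated activity (TIA) follows the piecewise scheme used in
post-therapy Lu-177 dosimetry protocols: constant activity A(t1) assumed
from injection to the first acquisition (a trapezoid with A(0) := A(t1)),
trapezoidal integration between the measured time points, and a
mono-exponential tail after the last point that considers only physical
decay:

    TIA = A(t1)*t1 + sum of trapezoids over [t1, tn] + A(tn)/lambda_phys

The physical-decay tail is deliberately conservative: it assumes no
biological clearance after the last scan, so regions clearing faster than
physical decay have their TIA overestimated. The TIA normalised to the
administered activity is the time-integrated activity coefficient (TIAC),
in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .nuclide import LU177_LAMBDA_PHYS


@dataclass
class TimeActivityCurve:
    """(time, activity) samples of one source region for one method."""

    times_h: np.ndarray
    activities_mbq: np.ndarray
    weights: np.ndarray | None = None
    method: str = "2D"
    region: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, float)
        self.activities_mbq = np.asarray(self.activities_mbq, float)
        if self.times_h.ndim != 1 or self.times_h.size < 2:
            raise ValueError("a TAC needs at least two time points")
        if np.any(np.diff(self.times_h) <= 0) or np.any(self.times_h <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if self.activities_mbq.shape != self.times_h.shape:
            raise ValueError("times and activities must have equal length")
        if np.any(self.activities_mbq < 0):
            raise ValueError("activities must be non-negative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != self.times_h.shape or np.any(self.weights <= 0):
                raise ValueError("weights must be positive and match the samples")


@dataclass(frozen=True)
class MonoExpFit:
    """A(t) = A0 * exp(-lambda * t) fitted to a TAC."""

    a0_mbq: float
    lambda_per_h: float
    residual_norm: float
    slower_than_physical: bool = False


@dataclass(frozen=True)
class PhysicalDecay:
    lambda_phys_per_h: float = LU177_LAMBDA_PHYS

    def __post_init__(self) -> None:
        if self.lambda_phys_per_h <= 0:
            raise ValueError("physical decay constant must be positive")


@dataclass(frozen=True)
class TiaResult:
    tia_mbq_h: float
    tiac_h: float
    administered_gbq: float
    method: str
    region: str


def fit_monoexponential(
    tac: TimeActivityCurve,
    *,
    lambda_phys: float = LU177_LAMBDA_PHYS,
) -> MonoExpFit:
    """Weighted least-squares mono-exponential regression of a TAC.

    Default weights are Poisson-like (1/max(A_i, eps)); with exactly two
    points the fit is exact. A fitted decay slower than physical decay is
    biologically impossible (it would imply continuing accumulation) and is
    flagged, not rejected.
    """
    t = tac.times_h
    a = tac.activities_mbq
    pos = a > 0
    if pos.sum() < 2:
        raise ValueError("mono-exponential fit needs >= 2 positive activities")
    if np.all(a == 0):
        raise ValueError("all activities are zero")
    w = tac.weights if tac.weights is not None else 1.0 / np.maximum(a, 1e-6)

    if pos.sum() == 2:
        (t1, t2), (a1, a2) = t[pos], a[pos]
        lam = np.log(a1 / a2) / (t2 - t1)
        a0 = a1 * np.exp(lam * t1)
        return MonoExpFit(float(a0), float(lam), 0.0, bool(lam < lambda_phys))

    # log-linear WLS start, then nonlinear WLS refinement
    ln_a = np.log(a[pos])
    coef = np.polyfit(t[pos], ln_a, 1, w=np.sqrt(w[pos] * a[pos] ** 2))
    lam0 = max(-coef[0], 1e-6)
    a00 = np.exp(coef[1])
    try:
        popt, _ = curve_fit(
            lambda tt, a0, lam: a0 * np.exp(-lam * tt),
            t,
            a,
            p0=(a00, lam0),
            sigma=1.0 / np.sqrt(w),
            absolute_sigma=False,
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"mono-exponential fit did not converge: {exc}") from exc
    a0, lam = float(popt[0]), float(popt[1])
    resid = a - a0 * np.exp(-lam * t)
    rnorm = float(np.sqrt(np.sum(w * resid**2)))
    if lam <= 0:
        warnings.warn("fitted decay constant is non-positive", stacklevel=2)
    return MonoExpFit(a0, lam, rnorm, bool(lam < lambda_phys))


def integrate_tia(
    tac: TimeActivityCurve,
    fit: MonoExpFit | None = None,
    decay: PhysicalDecay = PhysicalDecay(),
    *,
    first_interval: str = "constant",
) -> float:
    """Piecewise time-integrated activity in MBq*h.

    ``first_interval='constant'`` assumes A(0) = A(t1) (rectangle);
    ``'fit_a0'`` instead starts the first trapezoid from the fitted A0.
    The tail after the last time point always decays with the physical
    constant, regardless of the fitted clearance.
    """
    t = tac.times_h
    a = tac.activities_mbq
    if np.all(a == 0):
        return 0.0
    if first_interval == "constant":
        first = a[0] * t[0]
    elif first_interval == "fit_a0":
        if fit is None:
            fit = fit_monoexponential(tac)
        first = 0.5 * (fit.a0_mbq + a[0]) * t[0]
    else:
        raise ValueError("first_interval must be 'constant' or 'fit_a0'")
    middle = float(np.trapezoid(a, t))
    tail = a[-1] / decay.lambda_phys_per_h
    return float(first + middle + tail)


def hybrid_rescale(
    planar_tac: TimeActivityCurve,
    spect_activity_mbq: float,
    t_anchor_h: float,
    *,
    tolerance_h: float = 2.0,
) -> TimeActivityCurve:
    """Rescale a planar TAC so it matches one SPECT activity at the anchor.

    The whole curve is multiplied by s = A_SPECT / A_planar(t_anchor), so the
    kinetics (ratios between time points, hence any fitted decay constant)
    are preserved and only the absolute scale changes.
    """
    diffs = np.abs(planar_tac.times_h - t_anchor_h)
    idx = int(np.argmin(diffs))
    if diffs[idx] > tolerance_h:
        raise ValueError(
            f"anchor time {t_anchor_h} h not among planar time points "
            f"(closest: {planar_tac.times_h[idx]} h)"
        )
    a_anchor = planar_tac.activities_mbq[idx]
    if a_anchor <= 0:
        raise ValueError("planar activity at the anchor time must be positive")
    s = spect_activity_mbq / a_anchor
    return replace(
        planar_tac,
        activities_mbq=planar_tac.activities_mbq * s,
        method="hybrid",
    )


def compute_tiac(tia_mbq_h: float, administered_gbq: float) -> float:
    """TIAC in hours: TIA normalised to the administered activity."""
    if administered_gbq <= 0:
        raise ValueError("administered activity must be positive")
    return tia_mbq_h / (administered_gbq * 1000.0)


def tia_result(
    tac: TimeActivityCurve,
    administered_gbq: float,
    *,
    decay: PhysicalDecay = PhysicalDecay(),
    first_interval: str = "constant",
) -> TiaResult:
    """Convenience wrapper: fit, integrate and normalise one TAC."""
    fit = fit_monoexponential(tac) if np.count_nonzero(tac.activities_mbq) >= 2 else None
    tia = integrate_tia(tac, fit, decay, first_interval=first_interval)
    return TiaResult(
        tia_mbq_h=tia,
        tiac_h=compute_tiac(tia, administered_gbq),
        administered_gbq=administered_gbq,
        method=tac.method,
        region=tac.region,
    )
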