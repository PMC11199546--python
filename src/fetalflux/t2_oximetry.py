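"""Blood T2 relaxometry and T2 -> oxygen saturation conversion.

Blood T2 rises with oxygen saturation because deoxyhaemoglobin is
paramagnetic.  The signal of a T2-prepared acquisition decays
mono-exponentially with preparation time,

    S(t) = S0 * exp(-t / T2),

and the relaxation rate follows a quadratic-in-desaturation (Luz-Meiboom
family) calibration

    1/T2 = 1/T2_plateau + K * (1 - Y)^2,

where T2_plateau is the fully oxygenated blood T2 and K a field-, sequence-
and haematocrit-dependent rate constant.  The calibration constants shipped
as defaults are provisional and must be replaced by a site calibration for
quantitative use on real data.

ROI handling follows the central-60% convention: the vessel mask is eroded to
the deepest 60% of its area (distance-transform ranking) to avoid partial
volume at the lumen edge.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .types import (CalibrationModel, SaturationMeasurement, T2Fit, T2Series,
                    ValidationError)

__all__ = [
    "erode_to_central_fraction", "mean_roi_signal", "fit_t2",
    "t2_to_so2", "so2_to_t2", "recenter_roi",
]

T2_UPPER_BOUND_MS = 1e5


def erode_to_central_fraction(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the deepest ``fraction`` of a mask's area.

    Pixels are ranked by Euclidean distance to the mask boundary; the k
    deepest are retained, k being the largest count with k/n <= fraction
    (at least one pixel).  Ties are broken by distance rank then row-major
    index, making the result deterministic for any mask shape.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("mask is empty")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    k = max(1, int(np.floor(fraction * n + 1e-12)))
    if k >= n:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    idx = np.flatnonzero(mask)
    order = np.lexsort((idx, -dist.ravel()[idx]))   # depth desc, then row-major
    keep = idx[order[:k]]
    out = np.zeros_like(mask)
    out.ravel()[keep] = True
    return out


def mean_roi_signal(series: T2Series, roi: np.ndarray) -> np.ndarray:
    """Arithmetic mean of in-ROI pixel values at each preparation time."""
    roi = np.asarray(roi, dtype=bool)
    if not np.any(roi):
        raise ValidationError("ROI is empty")
    return series.images[:, roi].mean(axis=1)


def recenter_roi(series: T2Series, roi: np.ndarray) -> list[np.ndarray]:
    """Rigid translational ROI re-centring per prep image (off by default).

    Shifts the ROI so its centroid tracks the centroid of the
    above-threshold vessel signal in each frame; a light-weight stand-in for
    in-plane motion compensation on phantom data.
    """
    roi = np.asarray(roi, dtype=bool)
    base = np.array(ndimage.center_of_mass(roi))
    out = []
    for img in series.images:
        thr = img > 0.5 * img.max()
        target = np.array(ndimage.center_of_mass(thr)) if thr.any() else base
        shift = np.round(target - base).astype(int)
        out.append(np.roll(np.roll(roi, shift[0], axis=0), shift[1], axis=1))
    return out


def _loglinear_fit(signal: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    if np.any(signal <= 0):
        raise ValidationError("log-linear fit requires positive signals")
    slope, intercept = np.polyfit(t, np.log(signal), 1)
    if slope >= 0:
        return float(np.exp(intercept)), T2_UPPER_BOUND_MS
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_t2(signal_means: Sequence[float], prep_times_ms: Sequence[float],
           method: str = "iterative") -> T2Fit:
    """Fit S(t) = s0 * exp(-t/T2) to per-prep-time mean signals.

    ``method="loglinear"`` regresses log S on t (exact on noiseless data,
    mis-weighted under additive noise); ``method="iterative"`` minimises the
    sum of squared signal-domain residuals with ``scipy.optimize``
    (trust-region reflective), initialised from the log-linear solution so
    the two methods agree exactly when the data are noiseless.  A flat decay
    pins T2 at an upper bound and sets ``at_upper_bound``.
    """
    s = np.asarray(signal_means, dtype=float)
    t = np.asarray(prep_times_ms, dtype=float)
    if len(s) != len(t) or len(t) < 3:
        raise ValidationError("need >= 3 matched prep times and signals")

    s0_init, t2_init = _loglinear_fit(s, t)
    if method == "loglinear":
        s0_hat, t2_hat = s0_init, t2_init
    elif method == "iterative":
        if t2_init >= T2_UPPER_BOUND_MS:
            s0_hat, t2_hat = s0_init, T2_UPPER_BOUND_MS
        else:
            res = optimize.least_squares(
                lambda p: p[0] * np.exp(-t / p[1]) - s,
                x0=[s0_init, t2_init],
                bounds=([0.0, 1e-6], [np.inf, T2_UPPER_BOUND_MS]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if not res.success:
                raise ValidationError(
                    f"T2 fit did not converge (last iterate {res.x})")
            s0_hat, t2_hat = float(res.x[0]), float(res.x[1])
    else:
        raise ValidationError(f"unknown fit method: {method!r}")

    fitted = s0_hat * np.exp(-t / t2_hat)
    residuals = s - fitted
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0
    return T2Fit(s0=s0_hat, t2_ms=t2_hat, r_squared=r2, residuals=residuals,
                 method=method, at_upper_bound=t2_hat >= T2_UPPER_BOUND_MS)


def so2_to_t2(y: float, calib: CalibrationModel,
              hct: Optional[float] = None) -> float:
    """Forward calibration: T2 (ms) of blood at saturation ``y``."""
    if not 0.0 <= y <= 1.0:
        raise ValidationError("saturation must be in [0, 1]")
    k = calib.k_for_hct(hct)
    return 1.0 / (1.0 / calib.t2_plateau_ms + k * (1.0 - y) ** 2)


def t2_to_so2(t2_ms: float, calib: CalibrationModel, vessel: str = "",
              hct: Optional[float] = None,
              clamp_tolerance: float = 0.02) -> SaturationMeasurement:
    """Invert the calibration for the saturation root in [0, 1].

    Solving 1/T2 = 1/T2p + K (1-Y)^2 gives Y = 1 - sqrt((1/T2 - 1/T2p)/K);
    the positive square root is the only root with Y <= 1.  Unclamped roots
    outside [0, 1] by at most ``clamp_tolerance`` (measurement noise at the
    ends of the scale) are clamped with a flag; larger excursions raise.
    """
    if t2_ms <= 0:
        raise ValidationError("t2 must be positive")
    k = calib.k_for_hct(hct)
    excess = 1.0 / t2_ms - 1.0 / calib.t2_plateau_ms   # K (1-Y)^2
    if k == 0:
        if abs(excess) <= 1e-12:
            return SaturationMeasurement(vessel=vessel, y=1.0)
        raise ValidationError("K = 0 but t2 != t2_plateau: unidentifiable")
    if excess >= 0:
        y = 1.0 - float(np.sqrt(excess / k))
    else:
        # t2 above the fully saturated plateau: nominally unphysical
        y = 1.0 + float(np.sqrt(-excess / k))
    if y < -clamp_tolerance or y > 1.0 + clamp_tolerance:
        raise ValidationError(
            f"T2 {t2_ms:.1f} ms maps to saturation {y:.3f}, outside [0,1] "
            "beyond tolerance; check calibration")
    clamped = not (0.0 <= y <= 1.0)
    return SaturationMeasurement(vessel=vessel, y=float(np.clip(y, 0.0, 1.0)),
                                 clamped=clamped)
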