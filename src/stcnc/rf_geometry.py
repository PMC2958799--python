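"""Receptive-field center size from a linear filter.

The frame of maximal contrast deviation is fit with a rotated bivariate
Gaussian A * exp(-(a(x-h)^2 + 2b(x-h)(y-k) + c(y-k)^2)); the RF center
area is the 1-sigma ellipse area pi * sigma_a * sigma_b.  A direct
alternative counts checkers above a fraction of the peak magnitude; for a
radially symmetric Gaussian a threshold at fraction q of the peak traces
the sqrt(2 ln(1/q))-sigma contour, so the counted area divides by that
multiple squared to land on the same 1-sigma scale (1.5518 for q = 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .moments import LinearFilter

__all__ = [
    "GaussianFit",
    "RFArea",
    "max_contrast_frame",
    "fit_gaussian",
    "area_1sigma",
    "count_threshold_area",
    "sigma_contour_multiple",
    "measure_rf",
]


@dataclass
class GaussianFit:
    A: float
    h: float
    k: float
    sigma_a: float
    sigma_b: float
    theta: float
    residual: float
    converged: bool

    def __post_init__(self) -> None:
        # canonical form: major axis first, angle folded into [0, pi)
        if self.sigma_b > self.sigma_a:
            self.sigma_a, self.sigma_b = self.sigma_b, self.sigma_a
            self.theta += np.pi / 2
        self.theta = float(np.mod(self.theta, np.pi))


@dataclass
class RFArea:
    method: str  # gaussian_1sigma | threshold_count | threshold_count_corrected
    area_um2: float
    frame_index: int
    threshold_fraction: Optional[float] = None


def max_contrast_frame(filt: LinearFilter) -> tuple[int, np.ndarray]:
    """The single frame holding the element of global maximal |contrast|;
    ties resolve to the earliest frame."""
    arr = filt.as_3d
    if not np.any(arr):
        raise ValueError("zero filter has no maximal frame")
    idx = int(np.argmax(np.abs(arr)))
    fi = idx // (arr.shape[1] * arr.shape[2])
    return fi, arr[fi]


def _gauss2d(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    A, h, k, sa, sb, th = params
    ct, st = np.cos(th), np.sin(th)
    a = ct**2 / (2 * sa**2) + st**2 / (2 * sb**2)
    b = st * ct * (1.0 / (2 * sa**2) - 1.0 / (2 * sb**2))
    c = st**2 / (2 * sa**2) + ct**2 / (2 * sb**2)
    dx, dy = xx - h, yy - k
    return A * np.exp(-(a * dx**2 + 2 * b * dx * dy + c * dy**2))


def fit_gaussian(
    frame: np.ndarray,
    checker_size_um: float = 100.0,
    pad_border: int = 5,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> GaussianFit:
    """Least-squares rotated-Gaussian fit of a (windowed) filter frame.

    The frame is first embedded in ``pad_border`` rings of zero contrast,
    which loosely forces the fitted surface to zero at the window edges.
    Coordinates are micrometres, x along columns and y along rows, with
    the window's top-left checker center at origin_um + (cs/2, cs/2).
    Initialization comes from the thresholded-|z| centroid and second
    moments; frames whose peak is negative fit with A < 0.  Optimizer
    failure sets ``converged`` False instead of raising.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be at least 3x3")
    cs = checker_size_um
    z = np.pad(frame, pad_border)
    rows, cols = z.shape
    x = origin_um[0] + (np.arange(cols) - pad_border + 0.5) * cs
    y = origin_um[1] + (np.arange(rows) - pad_border + 0.5) * cs
    xx, yy = np.meshgrid(x, y)

    peak = np.abs(z).max()
    if peak == 0:
        return GaussianFit(0, 0, 0, cs, cs, 0, residual=0.0, converged=False)
    sign = np.sign(z.flat[np.argmax(np.abs(z))])
    w = np.maximum(sign * z, 0.0)
    w = np.where(w > 0.2 * peak, w, 0.0)
    tot = w.sum()
    h0 = float((w * xx).sum() / tot)
    k0 = float((w * yy).sum() / tot)
    var = max(
        float((w * ((xx - h0) ** 2 + (yy - k0) ** 2)).sum() / (2 * tot)), (0.3 * cs) ** 2
    )
    s0 = np.sqrt(var)
    p0 = np.array([sign * peak, h0, k0, s0, s0, 0.0])
    s_hi = max(rows, cols) * cs  # widths beyond the frame are unidentifiable
    p0[3:5] = np.clip(p0[3:5], 0.3 * cs, 0.9 * s_hi)
    lo = [-np.inf, x[0], y[0], 0.25 * cs, 0.25 * cs, -np.inf]
    hi = [np.inf, x[-1], y[-1], s_hi, s_hi, np.inf]
    try:
        res = least_squares(
            lambda p: (_gauss2d(p, xx, yy) - z).ravel(), p0, bounds=(lo, hi)
        )
        ok = res.status > 0
        A, h, k, sa, sb, th = res.x
        return GaussianFit(
            float(A), float(h), float(k), float(sa), float(sb), float(th),
            residual=float(2 * res.cost), converged=bool(ok),
        )
    except Exception:
        return GaussianFit(*p0, residual=np.inf, converged=False)


def area_1sigma(fit: GaussianFit) -> float:
    """Area of the 1-sigma ellipse, pi * sigma_a * sigma_b (um^2)."""
    if not fit.converged:
        raise ValueError("cannot take the area of a non-converged fit")
    return float(np.pi * fit.sigma_a * fit.sigma_b)


def count_threshold_area(
    frame: np.ndarray, checker_size_um: float = 100.0, fraction: float = 0.3
) -> RFArea:
    """Count checkers whose |contrast| exceeds fraction * max|contrast|;
    area = count * checker_size^2."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    frame = np.asarray(frame, dtype=float)
    peak = np.abs(frame).max()
    count = int((np.abs(frame) > fraction * peak).sum())
    return RFArea(
        method="threshold_count",
        area_um2=float(count * checker_size_um**2),
        frame_index=-1,
        threshold_fraction=fraction,
    )


def sigma_contour_multiple(fraction: float) -> float:
    """Radius, in sigma units, where a radially symmetric Gaussian falls to
    ``fraction`` of its peak: sqrt(2 ln(1/fraction)); 1.5518 at 0.3.

    Dividing a threshold-counted area by the square of this multiple
    converts it to the 1-sigma-contour scale of the Gaussian fit.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    return float(np.sqrt(2.0 * np.log(1.0 / fraction)))


def measure_rf(
    filt: LinearFilter,
    checker_size_um: float = 100.0,
    fraction: float = 0.3,
    pad_border: int = 5,
) -> tuple[GaussianFit, list[RFArea]]:
    """Both RF-size measures on the filter's maximal-contrast frame."""
    fi, frame = max_contrast_frame(filt)
    fit = fit_gaussian(frame, checker_size_um, pad_border=pad_border)
    out: list[RFArea] = []
    if fit.converged:
        out.append(
            RFArea(method="gaussian_1sigma", area_um2=area_1sigma(fit), frame_index=fi)
        )
    counted = count_threshold_area(frame, checker_size_um, fraction)
    counted.frame_index = fi
    out.append(counted)
    mult = sigma_contour_multiple(fraction)
    out.append(
        RFArea(
            method="threshold_count_corrected",
            area_um2=counted.area_um2 / mult**2,
            frame_index=fi,
            threshold_fraction=fraction,
        )
    )
    return fit, out
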