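"""Smoothing-spline fit and kinematic/dynamic curves for one blink.

The normalized intensity window is fitted with a natural cubic smoothing
spline *s* minimizing

    p * sum_i (I_i - s(t_i))^2  +  (1 - p) * integral (s'')^2 dt ,

the MATLAB-``csaps`` convention where ``p`` weights the residual (p = 1 is
pure interpolation, p = 0 the least-squares line; the study uses
p = 0.99996).  The smoothed curve is a proxy for eyelid position, so its
forward differences give lid velocity and acceleration, and their product the
power per unit mass developed by the eyelid muscles:

    v(t_i) = [s(t_{i+1}) - s(t_i)] / T                     (N-1 values)
    a(t_i) = [s(t_{i+2}) - 2 s(t_{i+1}) + s(t_i)] / T^2    (N-2 values)
    P(t_i) / m = v(t_i) * a(t_i)                           (N-2 values)

each also normalized by the maximum of its absolute value (v̂, â, P̂).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import DegenerateCurveError, InvalidInputError, InvalidParameterError
from .segmentation import BlinkSegment

__all__ = [
    "SmoothingResult",
    "BlinkKinematics",
    "smoothing_spline",
    "fit_smoothing_spline",
    "differentiate",
    "power_curve",
    "compute_kinematics",
    "normalize_intensity",
    "DEFAULT_P",
]

DEFAULT_P = 0.99996


def smoothing_spline(t: np.ndarray, y: np.ndarray, p: float) -> np.ndarray:
    """Natural cubic smoothing spline evaluated at the sample points.

    Solves min_s  p * ||y - s||^2 + (1 - p) * int (s'')^2  over natural cubic
    splines with knots at ``t`` via the Reinsch banded system: with the usual
    second-difference matrix Q (n x n-2) and penalty matrix R (tridiagonal),
    the interior second derivatives solve

        [R + ((1-p)/p) Q^T Q] gamma = Q^T y,    s = y - ((1-p)/p) Q gamma.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"smoothing parameter p must be in [0, 1], got {p}")
    n = len(t)
    if n != len(y):
        raise InvalidInputError("t and y must have equal length")
    if n < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("t must be strictly increasing with length >= 2")
    if p == 1.0 or n < 4:
        return y.copy()
    if p == 0.0:
        # Roughness term dominates: the least-squares straight line.
        coef = np.polyfit(t, y, 1)
        return np.polyval(coef, t)

    h = np.diff(t)
    m = n - 2
    # Q: columns are second divided-difference stencils at interior knots.
    rows = np.concatenate([np.arange(m), np.arange(1, m + 1), np.arange(2, m + 2)])
    cols = np.tile(np.arange(m), 3)
    vals = np.concatenate(
        [1.0 / h[:-1], -(1.0 / h[:-1] + 1.0 / h[1:]), 1.0 / h[1:]]
    )
    Q = sparse.csc_matrix((vals, (rows, cols)), shape=(n, m))
    R = sparse.diags(
        [h[1:-1] / 6.0, (h[:-1] + h[1:]) / 3.0, h[1:-1] / 6.0],
        offsets=[-1, 0, 1],
        format="csc",
    )
    lam = (1.0 - p) / p
    A = (R + lam * (Q.T @ Q)).tocsc()
    gamma = spsolve(A, Q.T @ y)
    return y - lam * (Q @ gamma)


def normalize_intensity(I: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Normalize an intensity window "to the unity".

    ``minmax`` (default) maps the window onto [0, 1] with 1 at the blink peak,
    making the curve a displacement proxy independent of light level;
    ``maxdiv`` divides by the window maximum.
    """
    I = np.asarray(I, dtype=float)
    if mode == "minmax":
        span = I.max() - I.min()
        if span <= 0:
            raise DegenerateCurveError("constant intensity window cannot be normalized")
        return (I - I.min()) / span
    if mode == "maxdiv":
        if I.max() == 0:
            raise DegenerateCurveError("all-zero intensity window cannot be normalized")
        return I / I.max()
    raise InvalidParameterError(f"unknown normalization mode '{mode}'")


@dataclass
class SmoothingResult:
    """Smoothed position proxy at the sample times, with the p used."""

    s: np.ndarray = field(repr=False)
    p: float


def fit_smoothing_spline(
    segment: BlinkSegment,
    p: float = DEFAULT_P,
    normalize: str = "minmax",
) -> SmoothingResult:
    """Normalize a blink segment's intensity and fit the smoothing spline."""
    if len(segment) < 4:
        raise InvalidInputError(
            f"segment must have at least 4 samples, got {len(segment)}"
        )
    I = normalize_intensity(segment.I_win, mode=normalize)
    s = smoothing_spline(segment.t_win, I, p)
    return SmoothingResult(s=s, p=p)


@dataclass
class BlinkKinematics:
    """Position proxy and its derivative curves for one blink window.

    ``v`` has N-1 samples, ``a`` and ``P`` N-2; sample ``i`` of each series is
    assigned to time ``t_i`` (forward differences).  ``v_max``, ``a_max`` and
    ``P_max`` hold the normalization divisors max|.| for de-normalization.
    """

    s: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    v_hat: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    a_hat: np.ndarray = field(repr=False)
    T: float
    v_max: float
    a_max: float
    P: np.ndarray | None = field(default=None, repr=False)
    P_hat: np.ndarray | None = field(default=None, repr=False)
    P_max: float | None = None

    @property
    def n(self) -> int:
        return len(self.s)

    def times(self, series: str = "s") -> np.ndarray:
        length = {"s": self.n, "v": self.n - 1, "a": self.n - 2, "P": self.n - 2}[
            series
        ]
        return np.arange(length) * self.T


def differentiate(smooth: SmoothingResult, T: float) -> BlinkKinematics:
    """Forward-difference velocity and acceleration with normalized variants."""
    if T <= 0:
        raise InvalidParameterError(f"frame period T must be positive, got {T}")
    s = np.asarray(smooth.s, dtype=float)
    v = np.diff(s) / T
    v_max = float(np.max(np.abs(v)))
    if v_max == 0:
        raise DegenerateCurveError(
            "velocity identically zero; v_hat normalization undefined"
        )
    a = np.diff(v) / T
    a_max = float(np.max(np.abs(a)))
    if a_max == 0:
        raise DegenerateCurveError(
            "acceleration identically zero; a_hat normalization undefined"
        )
    return BlinkKinematics(
        s=s,
        v=v,
        v_hat=v / v_max,
        a=a,
        a_hat=a / a_max,
        T=T,
        v_max=v_max,
        a_max=a_max,
    )


def power_curve(kin: BlinkKinematics) -> BlinkKinematics:
    """Fill P = v * a (power per unit mass) and its normalized form."""
    P = kin.v[:-1] * kin.a
    P_max = float(np.max(np.abs(P)))
    if P_max == 0:
        raise DegenerateCurveError(
            "power identically zero; P_hat normalization undefined"
        )
    kin.P = P
    kin.P_hat = P / P_max
    kin.P_max = P_max
    return kin


def compute_kinematics(
    segment: BlinkSegment,
    p: float = DEFAULT_P,
    normalize: str = "minmax",
) -> BlinkKinematics:
    """Normalize, smooth and differentiate a blink segment in one call."""
    smooth = fit_smoothing_spline(segment, p=p, normalize=normalize)
    return power_curve(differentiate(smooth, segment.T))
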