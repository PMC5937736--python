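"""Blink landmarks and the ordered 29-feature vector.

The normalized power curve P̂ of a well-formed blink traces four excursions
(+, -, +, -): muscle power peaks while closing (t1P), crosses zero at maximum
closure velocity (t2P), peaks again while braking the closure (t3P), returns
to zero when the eye is closed (t4P), and mirrors the pattern in the opening
phase (t5P..t7P) until the lid is retracted again (t8P).  Because muscle power
is zero while the eye is open, the first and last sustained departures of P̂
from zero give an objective blink start (t0) and end (t8P).

From these landmarks 29 features are assembled per blink, in a fixed
canonical order: eight power landmark times, four normalized power
magnitudes, four work integrals, three acceleration landmark times and their
magnitudes, three mechanical-impulse integrals, two normalized velocity
magnitudes, the fwhm of the displacement pulse, and the closure/opening
mean-velocity ratio S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateCurveError,
    InvalidIntervalError,
    MalformedBlinkError,
)
from .kinematics import DEFAULT_P, BlinkKinematics, compute_kinematics
from .segmentation import BlinkSegment

__all__ = [
    "FEATURE_NAMES",
    "BlinkLandmarks",
    "BlinkFeatureVector",
    "locate_landmarks",
    "work_integral",
    "impulse_integral",
    "fwhm",
    "velocity_ratio",
    "extract_features",
    "extract_many",
]

#: Canonical feature order (f = 1..29); frozen for all downstream modules.
FEATURE_NAMES = [
    "t1P", "t2P", "t3P", "t4P", "t5P", "t6P", "t7P", "t8P",
    "P_t1P", "P_t3P", "P_t5P", "P_t7P",
    "W_0_t2P", "W_t2P_t4P", "W_t4P_t6P", "W_t6P_t8P",
    "t1a", "t2a", "t3a",
    "a_t1a", "a_t2a", "a_t3a",
    "J_0_t2P", "J_t2P_t6P", "J_t6P_t8P",
    "v_t2P", "v_t6P",
    "fwhm", "S",
]

DEFAULT_ZERO_TOL = 0.01
DEFAULT_SUSTAIN = 3


@dataclass
class BlinkLandmarks:
    """Power/acceleration landmark times, reported relative to the blink start.

    ``t0_abs`` is the blink start on the window's own time axis; every other
    time is relative to it (the time scale is shifted so blinking starts at
    zero).  ``idx_*`` are sample-grid indices on the derivative grids, used to
    read normalized magnitudes without interpolation.
    """

    t0_abs: float
    t1P: float
    t2P: float
    t3P: float
    t4P: float
    t5P: float
    t6P: float
    t7P: float
    t8P: float
    t1a: float
    t2a: float
    t3a: float
    idx_t0: int
    idx_t1P: int
    idx_t3P: int
    idx_t5P: int
    idx_t7P: int
    idx_t8P: int
    idx_t1a: int
    idx_t2a: int
    idx_t3a: int

    def validate(self) -> None:
        chain = [0.0, self.t1P, self.t2P, self.t3P, self.t4P,
                 self.t5P, self.t6P, self.t7P, self.t8P]
        if np.any(np.diff(chain) <= 0):
            raise MalformedBlinkError(f"non-monotone power landmarks: {chain}")
        if not self.t1a < self.t2P:
            raise MalformedBlinkError("t1a must precede t2P")
        if not self.t2P < self.t2a < self.t4P:
            raise MalformedBlinkError("t2a must lie in (t2P, t4P)")
        if not self.t4P < self.t3a < self.t8P:
            raise MalformedBlinkError("t3a must lie in (t4P, t8P)")


@dataclass
class BlinkFeatureVector:
    """The ordered 29-feature vector for one blink of one subject/trial."""

    values: np.ndarray = field(repr=False)
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise MalformedBlinkError(
                f"feature vector must have {len(FEATURE_NAMES)} entries"
            )

    @property
    def names(self) -> list:
        return list(FEATURE_NAMES)

    def as_dict(self) -> dict:
        d = {"subject": self.subject_id, "trial": self.trial_id}
        d.update(zip(FEATURE_NAMES, self.values))
        return d


def _excursions(P: np.ndarray, tol: float, sustain: int) -> list:
    """Maximal sustained same-sign excursions of P beyond +-tol.

    Returns a list of (sign, start, end) with end inclusive.  Runs shorter
    than ``sustain`` are treated as noise blips; same-sign runs separated by a
    short gap (<= 2 * sustain samples) are merged into one excursion.
    """
    sign = np.zeros(len(P), dtype=int)
    sign[P > tol] = 1
    sign[P < -tol] = -1
    runs = []
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start]:
            if sign[start] != 0 and i - start >= sustain:
                runs.append([int(sign[start]), start, i - 1])
            start = i
    merged = []
    for r in runs:
        if merged and merged[-1][0] == r[0] and r[1] - merged[-1][2] <= 2 * sustain:
            merged[-1][2] = r[2]
        else:
            merged.append(r)
    return [tuple(r) for r in merged]


def _crossing(P: np.ndarray, lo: int, hi: int, T: float) -> float:
    """Linear-interpolated zero-crossing time of P within samples [lo, hi]."""
    for j in range(lo, hi):
        if P[j] == 0.0:
            return j * T
        if P[j] * P[j + 1] < 0:
            return (j + P[j] / (P[j] - P[j + 1])) * T
    raise MalformedBlinkError(f"no sign change of P in samples [{lo}, {hi}]")


def locate_landmarks(
    kin: BlinkKinematics,
    zero_tol: float = DEFAULT_ZERO_TOL,
    sustain: int = DEFAULT_SUSTAIN,
) -> BlinkLandmarks:
    """Locate the eight power landmarks and three acceleration landmarks.

    The blink is the unique run of four sustained P̂ excursions with signs
    (+, -, +, -) containing the global |P̂| extremum.  ``zero_tol`` (fraction
    of max |P̂|) sustained for ``sustain`` samples defines "different from
    zero"; zero crossings are linearly interpolated between samples, extremum
    times are reported at sample resolution.  Raises
    :class:`MalformedBlinkError` when the structure is absent.
    """
    if kin.P_hat is None:
        raise MalformedBlinkError("power curve not computed")
    P = kin.P_hat
    T = kin.T
    exc = _excursions(P, zero_tol, sustain)
    ipk = int(np.argmax(np.abs(P)))
    pattern = None
    for k in range(len(exc) - 3):
        window = exc[k : k + 4]
        if [e[0] for e in window] == [1, -1, 1, -1] and (
            window[0][1] <= ipk <= window[3][2]
        ):
            pattern = window
            break
    if pattern is None:
        raise MalformedBlinkError(
            "power curve lacks the (+,-,+,-) excursion structure of a blink"
        )
    e1, e2, e3, e4 = pattern

    # Blink start: sub-sample crossing of |P̂| through zero_tol entering the
    # first excursion (threshold crossings, like zero crossings, are well
    # defined between samples).
    i0 = e1[1]
    if i0 > 0 and abs(P[i0]) > zero_tol >= abs(P[i0 - 1]):
        frac = (zero_tol - abs(P[i0 - 1])) / (abs(P[i0]) - abs(P[i0 - 1]))
        t0_abs = (i0 - 1 + frac) * T
    else:
        t0_abs = i0 * T
    # Extremum of largest magnitude inside each excursion, sample resolution.
    def _extremum(e) -> int:
        seg = P[e[1] : e[2] + 1]
        return e[1] + int(np.argmax(np.abs(seg)))

    i1P, i3P, i5P, i7P = (_extremum(e) for e in pattern)
    t2P_abs = _crossing(P, e1[2], e2[1], T)
    t4P_abs = _crossing(P, e2[2], e3[1], T)
    t6P_abs = _crossing(P, e3[2], e4[1], T)

    # Blink end: first sustained return of |P̂| to zero after the opening
    # brake excursion.
    i8P = None
    quiet = np.abs(P) <= zero_tol
    for j in range(e4[2] + 1, len(P) - sustain + 1):
        if quiet[j : j + sustain].all():
            i8P = j
            break
    if i8P is None:
        raise MalformedBlinkError("power never returns to zero after the blink")
    if abs(P[i8P - 1]) > zero_tol >= abs(P[i8P]):
        frac = (abs(P[i8P - 1]) - zero_tol) / (abs(P[i8P - 1]) - abs(P[i8P]))
        t8P_abs = (i8P - 1 + frac) * T
    else:
        t8P_abs = i8P * T

    a = kin.a_hat
    lo1, hi1 = i0, int(np.floor(t2P_abs / T)) + 1
    lo2, hi2 = int(np.ceil(t2P_abs / T)), int(np.floor(t4P_abs / T)) + 1
    lo3, hi3 = int(np.ceil(t4P_abs / T)), i8P + 1
    if hi1 <= lo1 or hi2 <= lo2 or hi3 <= lo3:
        raise MalformedBlinkError("empty acceleration landmark search range")
    i1a = lo1 + int(np.argmax(a[lo1:hi1]))
    i2a = lo2 + int(np.argmin(a[lo2:hi2]))
    i3a = lo3 + int(np.argmax(a[lo3:hi3]))

    lm = BlinkLandmarks(
        t0_abs=t0_abs,
        t1P=i1P * T - t0_abs,
        t2P=t2P_abs - t0_abs,
        t3P=i3P * T - t0_abs,
        t4P=t4P_abs - t0_abs,
        t5P=i5P * T - t0_abs,
        t6P=t6P_abs - t0_abs,
        t7P=i7P * T - t0_abs,
        t8P=t8P_abs - t0_abs,
        t1a=i1a * T - t0_abs,
        t2a=i2a * T - t0_abs,
        t3a=i3a * T - t0_abs,
        idx_t0=i0,
        idx_t1P=i1P,
        idx_t3P=i3P,
        idx_t5P=i5P,
        idx_t7P=i7P,
        idx_t8P=i8P,
        idx_t1a=i1a,
        idx_t2a=i2a,
        idx_t3a=i3a,
    )
    lm.validate()
    return lm


def _interval_sum(y: np.ndarray, t_c: float, t_d: float, T: float) -> float:
    if not t_c < t_d:
        raise InvalidIntervalError(f"need t_c < t_d, got [{t_c}, {t_d}]")
    i_lo = int(np.ceil(t_c / T - 1e-9))
    i_hi = int(np.floor(t_d / T + 1e-9))
    i_lo = max(i_lo, 0)
    i_hi = min(i_hi, len(y) - 1)
    if i_hi < i_lo:
        raise InvalidIntervalError(
            f"interval [{t_c}, {t_d}] contains no samples at T={T}"
        )
    return float(np.sum(y[i_lo : i_hi + 1]))


def work_integral(P_hat: np.ndarray, t_c: float, t_d: float, T: float) -> float:
    """Work magnitude: rectangle-rule |T * sum P̂(t_i)| over t_c <= t_i <= t_d.

    ``P_hat`` is indexed on the uniform grid ``t_i = i * T`` of the blink
    window.  The magnitude is returned (work features are tabulated positive).
    """
    return abs(T * _interval_sum(np.asarray(P_hat, float), t_c, t_d, T))


def impulse_integral(a_hat: np.ndarray, t_c: float, t_d: float, T: float) -> float:
    """Mechanical impulse magnitude |T * sum â(t_i)| over t_c <= t_i <= t_d."""
    return abs(T * _interval_sum(np.asarray(a_hat, float), t_c, t_d, T))


def fwhm(s: np.ndarray, T: float, blink_start_index: int | None = None) -> float:
    """Full width at half maximum of the displacement pulse, in seconds.

    The open-eye baseline is the mean of ``s`` over samples before the blink
    start (or ``min(s)`` when no start index is given); the width is measured
    between the sub-sample linear crossings of baseline + half the pulse
    height on each side of the global maximum.
    """
    s = np.asarray(s, dtype=float)
    if blink_start_index is not None:
        if blink_start_index < 1:
            raise MalformedBlinkError("no pre-blink samples to estimate baseline")
        baseline = float(np.mean(s[:blink_start_index]))
    else:
        baseline = float(s.min())
    peak = float(s.max())
    if peak <= baseline:
        raise DegenerateCurveError("displacement pulse has no height above baseline")
    half = baseline + (peak - baseline) / 2.0
    imax = int(np.argmax(s))

    t_rise = None
    for j in range(imax - 1, -1, -1):
        if s[j] <= half:
            t_rise = (j + (half - s[j]) / (s[j + 1] - s[j])) * T
            break
    t_fall = None
    for j in range(imax + 1, len(s)):
        if s[j] <= half:
            t_fall = (j - 1 + (s[j - 1] - half) / (s[j - 1] - s[j])) * T
            break
    if t_rise is None or t_fall is None:
        raise MalformedBlinkError("half-maximum level not crossed on both sides")
    return t_fall - t_rise


def velocity_ratio(s: np.ndarray, lm: BlinkLandmarks, T: float) -> float:
    """Mean closure velocity over mean opening velocity,

        S = [(s(t4P) - s(t0)) * (t8P - t4P)] / [(s(t4P) - s(t8P)) * t4P],

    with the time origin at the blink start.  S > 1 means closure is faster.
    """
    s = np.asarray(s, dtype=float)
    t_grid = np.arange(len(s)) * T
    s_t0 = float(s[lm.idx_t0])
    s_t4P = float(np.interp(lm.t0_abs + lm.t4P, t_grid, s))
    s_t8P = float(s[min(lm.idx_t8P, len(s) - 1)])
    num = (s_t4P - s_t0) * (lm.t8P - lm.t4P)
    den = (s_t4P - s_t8P) * lm.t4P
    if den == 0:
        raise MalformedBlinkError("zero opening-phase denominator in S")
    return num / den


def assemble_features(
    kin: BlinkKinematics,
    lm: BlinkLandmarks,
    work_time_unit: float | None = None,
    subject_id: str = "",
    trial_id: str = "",
) -> BlinkFeatureVector:
    """Assemble the canonical 29-feature vector from curves and landmarks.

    Work and impulse integrals are expressed with ``work_time_unit`` (default:
    the kinematics' own sample period) as the time unit, i.e. the tabulated
    "a.u." scale where the integral of a unit curve over k frames is k.  A
    dense-grid oracle passes the coarse frame period here so its integrals are
    on the same scale as the pipeline's.
    """
    T = kin.T
    unit = work_time_unit if work_time_unit is not None else T
    P, a, v = kin.P_hat, kin.a_hat, kin.v_hat
    t0 = lm.t0_abs
    ab = lambda rel: t0 + rel  # landmark time on the window axis

    def w(tc, td):
        return work_integral(P, tc, td, T) / unit

    def j(tc, td):
        return impulse_integral(a, tc, td, T) / unit

    def v_at(rel):
        i = int(np.clip(round(ab(rel) / T), 0, len(v) - 1))
        return abs(float(v[i]))

    values = [
        lm.t1P, lm.t2P, lm.t3P, lm.t4P, lm.t5P, lm.t6P, lm.t7P, lm.t8P,
        abs(float(P[lm.idx_t1P])), abs(float(P[lm.idx_t3P])),
        abs(float(P[lm.idx_t5P])), abs(float(P[lm.idx_t7P])),
        w(t0, ab(lm.t2P)), w(ab(lm.t2P), ab(lm.t4P)),
        w(ab(lm.t4P), ab(lm.t6P)), w(ab(lm.t6P), ab(lm.t8P)),
        lm.t1a, lm.t2a, lm.t3a,
        abs(float(a[lm.idx_t1a])), abs(float(a[lm.idx_t2a])),
        abs(float(a[lm.idx_t3a])),
        j(t0, ab(lm.t2P)), j(ab(lm.t2P), ab(lm.t6P)), j(ab(lm.t6P), ab(lm.t8P)),
        v_at(lm.t2P), v_at(lm.t6P),
        fwhm(kin.s, T, blink_start_index=lm.idx_t0),
        velocity_ratio(kin.s, lm, T),
    ]
    return BlinkFeatureVector(
        values=np.array(values), subject_id=subject_id, trial_id=trial_id
    )


def extract_features(
    segment: BlinkSegment,
    p: float = DEFAULT_P,
    zero_tol: float = DEFAULT_ZERO_TOL,
    sustain: int = DEFAULT_SUSTAIN,
    normalize: str = "minmax",
) -> BlinkFeatureVector:
    """Run the full single-blink pipeline: smooth, differentiate, landmark,
    and assemble the 29 features in canonical order."""
    kin = compute_kinematics(segment, p=p, normalize=normalize)
    lm = locate_landmarks(kin, zero_tol=zero_tol, sustain=sustain)
    return assemble_features(
        kin, lm, subject_id=segment.subject_id, trial_id=segment.trial_id
    )


def extract_many(segments, **kwargs):
    """Extract features from many segments, excluding malformed blinks.

    Returns ``(vectors, exclusions)`` where exclusions is a list of
    ``(subject_id, trial_id, reason)`` for segments whose curves lack the
    canonical blink structure.
    """
    vectors, exclusions = [], []
    for seg in segments:
        try:
            vectors.append(extract_features(seg, **kwargs))
        except (MalformedBlinkError, DegenerateCurveError) as err:
            exclusions.append((seg.subject_id, seg.trial_id, str(err)))
    return vectors, exclusions
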