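"""Synthetic blink generator with closed-form ground truth.

Every pipeline stage is testable without recorded video: a blink is modelled
as the difference of two logistic ramps (a fast biphasic closure, a slower
opening — physiologically the closure takes roughly 0.15 s and the opening
0.25 s, and closures of 50–500 ms count as blinks).  Subjects differ in
timing/amplitude/steepness parameters; trials of one subject jitter those
parameters fractionally and add camera noise.  Blink spacing in full traces
is exponential ("Poisson-like") with a mean inter-blink interval near 6 s.

Because the waveform is closed-form, ground-truth landmarks and features can
be computed on a grid oversampled far beyond the camera rate, giving an
independent target for the 240 fps pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import InvalidProfileError, MalformedBlinkError, PlacementError
from .features import (
    DEFAULT_SUSTAIN,
    DEFAULT_ZERO_TOL,
    BlinkFeatureVector,
    BlinkLandmarks,
    assemble_features,
    extract_features,
    locate_landmarks,
)
from .ingest import FrameSequence, IntensityTrace, RegionOfInterest
from .kinematics import (
    DEFAULT_P as DEFAULT_SPLINE_P,
    SmoothingResult,
    differentiate,
    normalize_intensity,
    power_curve,
    smoothing_spline,
)
from .segmentation import DEFAULT_POST_S, DEFAULT_PRE_S, BlinkSegment

__all__ = [
    "SubjectProfile",
    "BlinkCurve",
    "GroundTruth",
    "TraceGroundTruth",
    "make_blink_curve",
    "ground_truth",
    "make_segment",
    "make_trace",
    "render_frames",
    "sample_profiles",
    "make_feature_dataset",
]

_DUR_LO, _DUR_HI = 0.05, 0.5


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-specific blink waveform parameters.

    Durations are in seconds and must stay within the physiological 50–500 ms
    band; ``jitter`` is the fractional standard deviation applied per
    parameter from trial to trial of one subject.
    """

    closure_duration_s: float = 0.15
    opening_duration_s: float = 0.25
    amplitude: float = 400.0
    baseline: float = 1000.0
    closure_sharpness: float = 10.0
    opening_sharpness: float = 10.0
    jitter: float = 0.08
    mean_interblink_s: float = 6.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise InvalidProfileError(f"amplitude must be positive, got {self.amplitude}")
        for name in ("closure_duration_s", "opening_duration_s"):
            d = getattr(self, name)
            if not _DUR_LO <= d <= _DUR_HI:
                raise InvalidProfileError(
                    f"{name}={d} outside physiological range "
                    f"[{_DUR_LO}, {_DUR_HI}] s"
                )
        if self.closure_sharpness <= 2 or self.opening_sharpness <= 2:
            raise InvalidProfileError("sharpness must exceed 2")
        if not 0 <= self.jitter < 0.5:
            raise InvalidProfileError(f"jitter must be in [0, 0.5), got {self.jitter}")


@dataclass(frozen=True)
class BlinkCurve:
    """Closed-form blink waveform: baseline + A*(rise logistic - fall logistic).

    The rise is centred half a closure-duration before the peak and the fall
    half an opening-duration after it, with steepness tau = duration /
    sharpness, so the lid is (nearly) fully closed exactly at ``t_peak``.
    """

    t_peak: float
    amplitude: float
    baseline: float
    mu_c: float
    tau_c: float
    mu_o: float
    tau_o: float

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.baseline + self.amplitude * (
            expit((t - self.mu_c) / self.tau_c)
            - expit((t - self.mu_o) / self.tau_o)
        )


def make_blink_curve(
    profile: SubjectProfile,
    t_peak: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BlinkCurve:
    """Instantiate the analytic waveform for one blink of one subject.

    When ``rng`` is given, each shape parameter is jittered by the profile's
    fractional intra-subject standard deviation (clipped back into the
    physiological band), emulating trial-to-trial variability.
    """
    c, o = profile.closure_duration_s, profile.opening_duration_s
    a = profile.amplitude
    kc, ko = profile.closure_sharpness, profile.opening_sharpness
    if rng is not None and profile.jitter > 0:
        j = profile.jitter
        c = float(np.clip(c * (1 + j * rng.standard_normal()), _DUR_LO, _DUR_HI))
        o = float(np.clip(o * (1 + j * rng.standard_normal()), _DUR_LO, _DUR_HI))
        a = float(a * max(0.1, 1 + j * rng.standard_normal()))
        kc = float(np.clip(kc * (1 + j * rng.standard_normal()), 4.0, 30.0))
        ko = float(np.clip(ko * (1 + j * rng.standard_normal()), 4.0, 30.0))
    return BlinkCurve(
        t_peak=t_peak,
        amplitude=a,
        baseline=profile.baseline,
        mu_c=t_peak - c / 2.0,
        tau_c=c / kc,
        mu_o=t_peak + o / 2.0,
        tau_o=o / ko,
    )


@dataclass
class GroundTruth:
    """Independent prediction of landmarks and features for an analytic blink.

    ``landmarks`` carries times resolved on the dense (oversampled) grid;
    ``features`` is the feature vector an ideal noise-free pipeline should
    output, i.e. the continuum-smoothed curve resampled at the camera grid
    and pushed through the camera-grid feature definitions (work/impulse
    rectangle sums and sample-grid magnitude readings are properties of the
    method at the camera rate, so the oracle reproduces them at that rate).
    """

    curve: BlinkCurve
    landmarks: BlinkLandmarks
    features: np.ndarray = field(repr=False)
    oversample: int = 100


def ground_truth(
    curve: BlinkCurve,
    fps: float = 240.0,
    oversample: int = 100,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    zero_tol: float = DEFAULT_ZERO_TOL,
    sustain: int = DEFAULT_SUSTAIN,
    p: float = DEFAULT_SPLINE_P,
) -> GroundTruth:
    """Landmarks/features of the analytic curve on an ``oversample``-times
    denser grid than the camera, using the same landmark definitions.

    The smoothing spline is part of the method's curve definition, so the
    dense grid is smoothed with the density-equivalent roughness weight
    (lambda scales with the number of points per unit time); with ``p=1`` the
    raw analytic curve is differentiated instead.  Work/impulse integrals are
    expressed in units of the *camera* frame period so they are directly
    comparable with pipeline features; ``sustain`` is likewise scaled to
    cover the same duration.
    """
    T = 1.0 / fps
    pre = int(round(pre_s * fps))
    post = int(round(post_s * fps))
    dt = T / oversample
    n_dense = (pre + post) * oversample + 1
    t = curve.t_peak - pre * T + np.arange(n_dense) * dt
    s = normalize_intensity(curve(t), mode="minmax")
    if p < 1.0:
        # Per-point residual weighting: lambda_dense = oversample * lambda.
        lam_dense = oversample * (1.0 - p) / p
        p_dense = 1.0 / (1.0 + lam_dense)
        s = smoothing_spline(t, s, p_dense)
    kin = power_curve(differentiate(SmoothingResult(s=s, p=p), dt))
    lm = locate_landmarks(kin, zero_tol=zero_tol, sustain=sustain * oversample)

    # Ideal-pipeline features: the continuum curve observed at the camera
    # grid (the dense grid contains the camera samples exactly).
    s_cam = s[::oversample]
    kin_cam = power_curve(differentiate(SmoothingResult(s=s_cam, p=p), T))
    lm_cam = locate_landmarks(kin_cam, zero_tol=zero_tol, sustain=sustain)
    fv = assemble_features(kin_cam, lm_cam, work_time_unit=T)
    return GroundTruth(curve=curve, landmarks=lm, features=fv.values,
                       oversample=oversample)


def make_segment(
    profile: SubjectProfile,
    subject_id: str = "s0",
    trial_id: str = "t0",
    fps: float = 240.0,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
    with_truth: bool = False,
):
    """Sample one cropped blink window directly (no full trace needed).

    ``noise_sd`` is the camera-noise standard deviation as a fraction of the
    blink amplitude.  Returns the segment, or ``(segment, GroundTruth)`` when
    ``with_truth`` — the truth is computed on the jittered (noise-free)
    analytic curve.
    """
    T = 1.0 / fps
    pre = int(round(pre_s * fps))
    post = int(round(post_s * fps))
    curve = make_blink_curve(profile, t_peak=pre * T, rng=rng)
    t = np.arange(pre + post + 1) * T
    I = curve(t)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        I = I + noise_sd * curve.amplitude * rng.standard_normal(len(t))
    seg = BlinkSegment(
        subject_id=subject_id,
        trial_id=trial_id,
        I_win=I,
        t_win=t,
        peak_offset=pre,
        T=T,
    )
    if with_truth:
        return seg, ground_truth(curve, fps=fps, pre_s=pre_s, post_s=post_s)
    return seg


@dataclass
class TraceGroundTruth:
    """True peak placement for every blink in a generated trace."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    curves: list


def make_trace(
    profiles,
    duration_s: float = 20.0,
    fps: float = 240.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    n_blinks: int | None = None,
    margin_s: float = 0.1,
):
    """Generate a full intensity trace with blinks at recorded positions.

    ``profiles`` is one :class:`SubjectProfile` or a list cycled across
    blinks.  Peaks are placed left to right with exponential inter-blink
    gaps (mean ``mean_interblink_s``) floored at the crop window length, so
    windows never overlap; with ``n_blinks`` given, exactly that many blinks
    are placed (evenly spaced jittered) or :class:`PlacementError` is raised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(profiles, SubjectProfile):
        profiles = [profiles]
    T = 1.0 / fps
    n = int(round(duration_s * fps))
    t = np.arange(n) * T
    lo = DEFAULT_PRE_S + margin_s
    hi = duration_s - DEFAULT_POST_S - margin_s
    min_gap = DEFAULT_PRE_S + DEFAULT_POST_S + margin_s

    peaks = []
    if n_blinks is not None:
        span = hi - lo
        if n_blinks < 1 or (n_blinks - 1) * min_gap > span:
            raise PlacementError(
                f"cannot place {n_blinks} blinks with gap {min_gap:.2f}s "
                f"in {span:.2f}s"
            )
        base = np.linspace(lo, hi, n_blinks)
        wiggle = 0.25 * min_gap
        peaks = list(base + rng.uniform(-wiggle, wiggle, size=n_blinks)) if (
            n_blinks > 1
        ) else [float(base[0]) ]
    else:
        pos = lo + rng.exponential(profiles[0].mean_interblink_s)
        while pos <= hi:
            peaks.append(pos)
            pos += max(min_gap, rng.exponential(profiles[0].mean_interblink_s))
        if not peaks:
            if hi <= lo:
                raise PlacementError(
                    f"a {duration_s}s trace is shorter than one crop window"
                )
            # condition on at least one blink occurring in the recording
            peaks = [float(rng.uniform(lo, hi))]

    # Snap peaks onto the sample grid so detection targets are exact.
    peak_indices = np.array([int(round(p / T)) for p in peaks])
    peak_times = peak_indices * T

    baseline = profiles[0].baseline
    I = np.full(n, baseline)
    curves = []
    for k, tp in enumerate(peak_times):
        prof = profiles[k % len(profiles)]
        curve = make_blink_curve(prof, t_peak=float(tp),
                                 rng=rng if prof.jitter > 0 else None)
        curves.append(curve)
        I = I + (curve(t) - curve.baseline)
    if noise_sd > 0:
        I = I + noise_sd * profiles[0].amplitude * rng.standard_normal(n)
    trace = IntensityTrace(t=t, I=I, T=T)
    return trace, TraceGroundTruth(
        peak_times=peak_times, peak_indices=peak_indices, curves=curves
    )


def render_frames(
    trace: IntensityTrace,
    frame_shape: tuple = (24, 32),
    margin: int = 4,
    spatial_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Render frames whose ROI pixel sum reproduces the trace exactly.

    Each frame is a dark border around a uniform active region holding
    ``I[k] / n_pixels`` per pixel; optional spatial noise is constructed to
    sum to zero so the ROI sum is preserved.  Returns ``(FrameSequence,
    RegionOfInterest)`` for end-to-end ingest tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = frame_shape
    roi = RegionOfInterest(margin, margin + h, margin, margin + w)
    npix = h * w
    frames = []
    for Ik in trace.I:
        frame = np.zeros((h + 2 * margin, w + 2 * margin))
        block = np.full((h, w), Ik / npix)
        if spatial_noise > 0:
            noise = spatial_noise * rng.standard_normal((h, w))
            noise -= noise.mean()  # zero-sum: ROI total unchanged
            block = block + noise
        frame[margin : margin + h, margin : margin + w] = block
        frames.append(frame)
    return FrameSequence(frames=frames, fps=trace.fps), roi


def sample_profiles(
    n_subjects: int,
    seed: int | np.random.Generator = 0,
    base: SubjectProfile | None = None,
    subject_spread: float = 0.15,
) -> list:
    """Draw a population of subject profiles around ``base``.

    Inter-subject spread is lognormal-ish (fractional sd ``subject_spread``)
    on durations, amplitude and steepness; intra-subject jitter is inherited
    from ``base``.  Closure is kept faster than opening, the physiological
    default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = base or SubjectProfile()
    profiles = []
    for _ in range(n_subjects):
        for _attempt in range(100):
            c = float(np.clip(
                base.closure_duration_s * np.exp(subject_spread * rng.standard_normal()),
                0.08, 0.3))
            o = float(np.clip(
                base.opening_duration_s * np.exp(subject_spread * rng.standard_normal()),
                0.12, 0.45))
            if c < o:
                break
        profiles.append(replace(
            base,
            closure_duration_s=c,
            opening_duration_s=o,
            amplitude=float(base.amplitude * np.exp(subject_spread * rng.standard_normal())),
            closure_sharpness=float(np.clip(
                base.closure_sharpness * (1 + subject_spread * rng.standard_normal()),
                5.0, 20.0)),
            opening_sharpness=float(np.clip(
                base.opening_sharpness * (1 + subject_spread * rng.standard_normal()),
                5.0, 20.0)),
        ))
    return profiles


def make_feature_dataset(
    n_subjects: int = 26,
    trials: int = 74,
    fps: float = 240.0,
    noise_sd: float = 0.02,
    subject_spread: float = 0.15,
    seed: int = 0,
    max_retries: int = 25,
    return_segments: bool = False,
    **extract_kwargs,
):
    """Simulate the study geometry: n subjects x b trials of extracted features.

    Each trial is a jittered, noisy blink window run through the real feature
    pipeline.  Trials whose noise destroys the canonical landmark structure
    are redrawn (up to ``max_retries``), mirroring how a recording session
    simply keeps collecting blinks until enough clean ones exist.

    Returns ``(FeatureDataset, profiles)`` or ``(dataset, profiles,
    segments_by_subject)`` with ``return_segments``.
    """
    from .data import FeatureDataset

    ss = np.random.SeedSequence(seed)
    rng_pop, rng_trials = (np.random.default_rng(s) for s in ss.spawn(2))
    profiles = sample_profiles(n_subjects, seed=rng_pop,
                               subject_spread=subject_spread)
    vectors = []
    segments_by_subject: dict = {}
    for j, prof in enumerate(profiles):
        sid = f"S{j:02d}"
        segs = []
        for k in range(trials):
            for attempt in range(max_retries):
                seg = make_segment(
                    prof, subject_id=sid, trial_id=f"T{k:03d}",
                    fps=fps, noise_sd=noise_sd, rng=rng_trials,
                )
                try:
                    vec = extract_features(seg, **extract_kwargs)
                except MalformedBlinkError:
                    continue
                vectors.append(vec)
                segs.append(seg)
                break
            else:
                raise MalformedBlinkError(
                    f"subject {sid} trial {k}: no clean blink in "
                    f"{max_retries} draws"
                )
        segments_by_subject[sid] = segs
    ds = FeatureDataset.from_vectors(vectors)
    if return_segments:
        return ds, profiles, segments_by_subject
    return ds, profiles
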