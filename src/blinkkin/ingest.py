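"""Video-to-intensity ingestion.

A blink appears in a high-speed eye video as a transient rise of the light
reflected by the eyelid: the lid reflects more light than the pupil/iris, so
summing the pixel intensities inside a rectangular region of interest (ROI)
around the eye yields a scalar per frame that acts as a proxy for eyelid
position (peak = eye closed).  This module turns a frame sequence plus an ROI
into that uniformly sampled intensity time series.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "FrameSequence",
    "RegionOfInterest",
    "IntensityTrace",
    "extract_intensity",
    "read_frame_directory",
    "read_video",
]

# Rec. 601 luma weights, the common grayscale conversion for consumer video.
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(float) @ _LUMA
    raise InvalidInputError(f"frame has unsupported shape {frame.shape}")


@dataclass
class FrameSequence:
    """Ordered grayscale frames at a fixed frame rate.

    Parameters
    ----------
    frames : list of 2-D arrays
        Pixel intensity counts; all frames must share one shape.
    fps : float
        Frame rate in Hz (the study camera ran at 240 fps).
    """

    frames: list
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidInputError(f"fps must be positive, got {self.fps}")
        if len(self.frames) < 2:
            raise InvalidInputError(
                f"need at least 2 frames, got {len(self.frames)}"
            )
        self.frames = [np.asarray(_to_gray(np.asarray(f))) for f in self.frames]
        shape0 = self.frames[0].shape
        for k, f in enumerate(self.frames):
            if f.shape != shape0:
                raise InvalidInputError(
                    f"frame {k} has shape {f.shape}, expected {shape0}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames[0].shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel region, 0-based half-open intervals."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start:
            raise InvalidInputError(
                f"empty ROI rows [{self.row_start}, {self.row_stop})"
            )
        if self.col_stop <= self.col_start:
            raise InvalidInputError(
                f"empty ROI cols [{self.col_start}, {self.col_stop})"
            )
        if self.row_start < 0 or self.col_start < 0:
            raise InvalidInputError("ROI indices must be non-negative")

    def validate_for(self, shape: tuple) -> None:
        nrow, ncol = shape[:2]
        if self.row_stop > nrow:
            raise InvalidInputError(
                f"ROI row_stop {self.row_stop} exceeds frame height {nrow}"
            )
        if self.col_stop > ncol:
            raise InvalidInputError(
                f"ROI col_stop {self.col_stop} exceeds frame width {ncol}"
            )

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.row_start : self.row_stop, self.col_start : self.col_stop]


@dataclass
class IntensityTrace:
    """Uniformly sampled ROI-summed reflected-light signal.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, ``t[k] = k / fps``.
    I : ndarray
        Summed pixel intensity per frame (arbitrary units).
    T : float
        Frame period in seconds, ``1 / fps``.
    """

    t: np.ndarray
    I: np.ndarray = field(repr=False)
    T: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape or self.t.ndim != 1:
            raise InvalidInputError(
                f"t and I must be 1-D and equal length, got {self.t.shape} "
                f"and {self.I.shape}"
            )
        if self.T <= 0:
            raise InvalidInputError(f"frame period T must be positive, got {self.T}")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, self.T, rtol=1e-6, atol=1e-9):
                raise InvalidInputError(
                    "sample times must be strictly increasing with uniform "
                    f"spacing T={self.T}"
                )

    @property
    def fps(self) -> float:
        return 1.0 / self.T

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "intensity": self.I}).to_csv(
            path, index=False
        )

    @classmethod
    def read_csv(cls, path) -> "IntensityTrace":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("time_s", "intensity"):
            if col not in df.columns:
                raise InvalidInputError(f"trace CSV missing column '{col}'")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise InvalidInputError("trace CSV must contain at least 2 samples")
        return cls(t=t, I=df["intensity"].to_numpy(float), T=float(t[1] - t[0]))


def extract_intensity(frames: FrameSequence, roi: RegionOfInterest) -> IntensityTrace:
    """Sum pixel intensities inside *roi* for every frame.

    Returns an :class:`IntensityTrace` with ``I[k]`` the ROI pixel sum of
    frame *k* and ``t[k] = k / fps``.
    """
    roi.validate_for(frames.frame_shape)
    I = np.array([float(roi.crop(f).sum()) for f in frames.frames])
    T = 1.0 / frames.fps
    t = np.arange(len(frames)) * T
    return IntensityTrace(t=t, I=I, T=T)


_FRAME_EXT = (".png", ".tif", ".tiff")


def read_frame_directory(path, fps: float) -> FrameSequence:
    """Load a directory of numbered PNG/TIFF frames, sorted by index."""
    import imageio.v3 as iio

    names = [n for n in os.listdir(path) if n.lower().endswith(_FRAME_EXT)]
    if not names:
        raise InvalidInputError(f"no PNG/TIFF frames found in {path}")

    def key(name: str):
        m = re.search(r"(\d+)", name)
        return (int(m.group(1)) if m else 0, name)

    frames = [iio.imread(os.path.join(path, n)) for n in sorted(names, key=key)]
    return FrameSequence(frames=frames, fps=fps)


def read_video(path, fps: float | None = None) -> FrameSequence:
    """Load an MP4/AVI container through imageio.

    ``fps`` overrides the container metadata when given (sports cameras often
    store a playback rate that differs from the capture rate).
    """
    import imageio.v2 as iio

    reader = iio.get_reader(path)
    meta = reader.get_meta_data()
    frames = [np.asarray(f) for f in reader]
    reader.close()
    rate = fps if fps is not None else meta.get("fps")
    if not rate or rate <= 0:
        raise InvalidInputError(
            "frame rate not present in video metadata; pass fps explicitly"
        )
    return FrameSequence(frames=frames, fps=float(rate))
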