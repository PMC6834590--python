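"""Frame-difference behavioral activity.

Movement of a worm inside a chamber is quantified by subtracting
consecutive video frames and counting the pixels whose grey value changes
by more than a noise threshold.  A moving animal flips many pixels per
frame pair; a quiescent animal flips almost none.  The raw per-frame-pair
counts are then smoothed and normalized to a high percentile so that a
single quiescence threshold can be applied across animals and fields of
view with different brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionOfInterest",
    "ActivityTrace",
    "frame_difference_activity",
    "normalize_activity",
    "activity_trace",
    "moving_average",
]


class DegenerateTraceError(ValueError):
    """Raised when a trace cannot be normalized (e.g. all-zero activity)."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular per-animal region, 0-based half-open pixel bounds."""

    animal_id: str
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1)

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.rect
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"empty ROI rect {self.rect}")

    def slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.rect
        return slice(r0, r1), slice(c0, c1)


@dataclass
class ActivityTrace:
    """Raw and normalized movement activity for one animal.

    ``raw[t]`` is the number of pixels changing between frames ``t`` and
    ``t + 1``, so both series have ``n_frames - 1`` samples; sample ``t``
    is assigned time ``t / fps``.
    """

    animal_id: str
    fps: float
    raw: np.ndarray
    normalized: np.ndarray
    smoothing_window_s: float
    pixel_delta_threshold: float
    norm_percentile: float = 95.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.raw.size) / self.fps


def frame_difference_activity(
    video: np.ndarray,
    roi: RegionOfInterest | None = None,
    pixel_delta_threshold: float = 30,
) -> np.ndarray:
    """Count pixels changing by strictly more than the threshold per frame pair.

    Parameters
    ----------
    video : array of shape (n_frames, h, w)
        Grayscale stack, integer or float grey levels.
    roi : optional region restricting the count to one animal's chamber.
    pixel_delta_threshold : grey levels; a pixel counts only if
        ``|frame[t+1] - frame[t]| > threshold`` (strict).

    Returns
    -------
    raw activity, shape (n_frames - 1,), dtype int64.
    """
    video = np.asarray(video)
    if video.ndim != 3 or video.shape[0] < 2:
        raise ValueError("need a (n_frames, h, w) stack with at least 2 frames")
    if pixel_delta_threshold <= 0:
        raise ValueError("pixel_delta_threshold must be > 0")
    if roi is not None:
        r0, c0, r1, c1 = roi.rect
        h, w = video.shape[1:]
        if r1 > h or c1 > w or r0 < 0 or c0 < 0:
            raise ValueError(f"ROI {roi.rect} outside frame bounds {(h, w)}")
        video = video[:, r0:r1, c0:c1]
    # widen before subtraction so unsigned frames cannot wrap around
    frames = video.astype(np.int64) if np.issubdtype(video.dtype, np.integer) else video
    delta = np.abs(np.diff(frames, axis=0))
    return np.count_nonzero(delta > pixel_delta_threshold, axis=(1, 2)).astype(np.int64)


def moving_average(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving average with the window truncated at the edges."""
    x = np.asarray(x, dtype=float)
    if window_frames <= 1:
        return x.copy()
    kernel = np.ones(window_frames)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def normalize_activity(
    raw: np.ndarray,
    fps: float,
    smoothing_window_s: float = 20.0,
    norm_percentile: float = 95.0,
) -> np.ndarray:
    """Smooth a raw activity series and scale it by a high percentile.

    The series is smoothed with a centered moving average over
    ``round(smoothing_window_s * fps)`` frames (no smoothing if the window
    is zero, used for fine-timescale stimulus analysis) and divided by its
    ``norm_percentile``-th percentile (linear interpolation between order
    statistics).  Values are approximately in [0, 1]; the top tail may
    exceed 1 and is deliberately not clipped.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("raw activity series is empty")
    if not (0 < norm_percentile <= 100):
        raise ValueError("norm_percentile must be in (0, 100]")
    if smoothing_window_s < 0:
        raise ValueError("smoothing_window_s must be >= 0")
    window = int(round(smoothing_window_s * fps)) if smoothing_window_s > 0 else 0
    smoothed = moving_average(raw, window) if window > 1 else raw.astype(float)
    scale = np.percentile(smoothed, norm_percentile)
    if scale <= 0:
        raise DegenerateTraceError(
            "normalization percentile is zero (all-quiet trace); cannot divide"
        )
    return smoothed / scale


def activity_trace(
    video: np.ndarray,
    roi: RegionOfInterest,
    fps: float,
    pixel_delta_threshold: float = 30,
    smoothing_window_s: float = 20.0,
    norm_percentile: float = 95.0,
) -> ActivityTrace:
    """Full video -> :class:`ActivityTrace` convenience wrapper."""
    raw = frame_difference_activity(video, roi, pixel_delta_threshold)
    normalized = normalize_activity(raw, fps, smoothing_window_s, norm_percentile)
    return ActivityTrace(
        animal_id=roi.animal_id,
        fps=fps,
        raw=raw,
        normalized=normalized,
        smoothing_window_s=smoothing_window_s,
        pixel_delta_threshold=pixel_delta_threshold,
        norm_percentile=norm_percentile,
    )
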