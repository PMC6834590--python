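"""Fluorescence-trace processing for whole-brain and RIS calcium imaging.

Two baseline conventions are implemented.  Single-channel traces use a
running-minimum baseline: dF/F(t) = [F(t) - F0(t)] / F0(t) with F0(t) the
minimum fluorescence observed up to time t, which makes dF/F non-negative
and robust to slow photobleaching.  Two-color (GCaMP/mKate) recordings
form the ratio R = (dF/F)_GCaMP / (dF/F)_mKate and report
dR/R = [R(t) - R0] / R0 with R0 the lower 20th-percentile value of R;
the ratio cancels motion and bleaching common to both channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .activity import moving_average, normalize_activity
from .sleep import BoutSet

__all__ = [
    "FluorTrace",
    "RatioTrace",
    "extract_neuron_trace",
    "extract_ris_trace",
    "delta_f_over_f",
    "delta_r_over_r",
    "displacement_behavior",
    "state_fluorescence_summary",
    "windowed_correlation",
]


class DegenerateBaselineError(ValueError):
    """Raised when a fluorescence baseline is non-positive."""


@dataclass
class FluorTrace:
    """Single-channel fluorescence with running-minimum baseline."""

    times_s: np.ndarray
    F: np.ndarray  # smoothed raw fluorescence, a.u.
    F0: np.ndarray  # running minimum of F, non-increasing
    dFF: np.ndarray  # (F - F0) / F0, >= 0


@dataclass
class RatioTrace:
    """Two-channel ratio with percentile baseline."""

    times_s: np.ndarray
    R: np.ndarray
    R0: float
    dRR: np.ndarray


def extract_neuron_trace(video: np.ndarray, center: tuple[int, int], roi_half_px: int = 4) -> np.ndarray:
    """Mean pixel value of a square ROI around a neuron, per frame.

    The default half-size of 4 px gives the 8 x 8 window used for
    hand-tracked neurons in whole-brain recordings.
    """
    video = np.asarray(video)
    r, c = center
    h, w = video.shape[1:]
    r0, r1 = r - roi_half_px, r + roi_half_px
    c0, c1 = c - roi_half_px, c + roi_half_px
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"ROI around {center} clipped by frame edge {(h, w)}")
    return video[:, r0:r1, c0:c1].mean(axis=(1, 2))


def extract_ris_trace(frame: np.ndarray, soma_centroid: tuple[int, int], window_px: int = 25, n_top: int = 20) -> float:
    """Mean of the ``n_top`` brightest pixels in a window around the RIS soma.

    Averaging the 20 largest values inside a 25 x 25 px window tracks the
    soma signal despite small centroid errors.  Windows clipped by the
    frame edge are padded with the edge values (with a warning).
    """
    frame = np.asarray(frame, dtype=float)
    half = window_px // 2
    r, c = int(round(soma_centroid[0])), int(round(soma_centroid[1]))
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    h, w = frame.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        warnings.warn("RIS window clipped by frame edge; padding with edge values")
        pad = max(-r0, -c0, r1 - h, c1 - w, 0)
        frame = np.pad(frame, pad, mode="edge")
        r0, r1, c0, c1 = r0 + pad, r1 + pad, c0 + pad, c1 + pad
    window = frame[r0:r1, c0:c1].ravel()
    top = np.partition(window, -n_top)[-n_top:]
    return float(top.mean())


def delta_f_over_f(F: np.ndarray, fps: float = 1.0, smooth_s: float = 3.0) -> FluorTrace:
    """Running-minimum dF/F after optional 3-s moving-average smoothing."""
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("empty fluorescence series")
    window = int(round(smooth_s * fps)) if smooth_s > 0 else 0
    smoothed = moving_average(F, window) if window > 1 else F.astype(float)
    F0 = np.minimum.accumulate(smoothed)
    if F0[0] <= 0 or (F0 <= 0).any():
        raise DegenerateBaselineError("running-minimum baseline is non-positive")
    dFF = (smoothed - F0) / F0
    return FluorTrace(times_s=np.arange(F.size) / fps, F=smoothed, F0=F0, dFF=dFF)


def delta_r_over_r(gcamp: FluorTrace, mkate: FluorTrace, denom_floor: float = 0.01, r0_percentile: float = 20.0) -> RatioTrace:
    """GCaMP/mKate ratio normalized to its lower-percentile baseline.

    The mKate dF/F is exactly zero wherever its running minimum is
    attained, so the denominator is floored at ``denom_floor`` before
    dividing.  R0 is the ``r0_percentile``-th percentile of R (linear
    interpolation, matching the activity-normalization convention).
    """
    if gcamp.dFF.size != mkate.dFF.size:
        raise ValueError("channel traces have different lengths")
    if denom_floor <= 0:
        raise ValueError("denom_floor must be > 0")
    if not np.any(mkate.dFF > 0):
        raise DegenerateBaselineError("mKate dF/F is identically zero")
    R = gcamp.dFF / np.maximum(mkate.dFF, denom_floor)
    R0 = float(np.percentile(R, r0_percentile))
    if R0 == 0:
        raise DegenerateBaselineError("ratio baseline R0 is zero")
    return RatioTrace(times_s=gcamp.times_s, R=R, R0=R0, dRR=(R - R0) / R0)


def displacement_behavior(
    tracked_positions: np.ndarray,
    fps: float,
    smoothing_window_s: float = 3.0,
    norm_percentile: float = 95.0,
    normalize: bool = True,
) -> np.ndarray:
    """Behavior metric from hand-tracked neuron positions.

    ``tracked_positions`` has shape (n_frames, n_neurons, 2); the raw
    metric is the mean Euclidean displacement of the neurons between
    consecutive frames.  Frames with missing (NaN) positions are excluded
    from the mean with a warning.  The series is smoothed and normalized
    like a frame-difference activity trace unless ``normalize`` is false.
    """
    pos = np.asarray(tracked_positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 2 or pos.shape[1] < 1:
        raise ValueError("expected positions of shape (n_frames, n_neurons, 2)")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=2)  # (n_frames-1, n_neurons)
    if np.isnan(step).any():
        warnings.warn("missing neuron positions; affected neurons excluded per frame")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nanmean(step, axis=1)
    raw = np.nan_to_num(raw, nan=0.0)
    if not normalize:
        return raw
    return normalize_activity(raw, fps, smoothing_window_s, norm_percentile)


def state_fluorescence_summary(series: np.ndarray, bouts: BoutSet, fps: float) -> tuple[float | None, float | None]:
    """Mean of a dF/F or dR/R series over wake vs. sleep frames."""
    series = np.asarray(series, dtype=float)
    in_sleep = bouts.in_bout_mask(series.size, fps)
    wake = float(series[~in_sleep].mean()) if (~in_sleep).any() else None
    sleep = float(series[in_sleep].mean()) if in_sleep.any() else None
    return wake, sleep


def windowed_correlation(
    behavior: np.ndarray,
    fluor: np.ndarray,
    window_s: float,
    fps: float,
    n_shuffles: int = 0,
    seed: int | None = None,
    exclude_identity: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window Pearson correlation of fluorescence with behavior.

    Both series are split into non-overlapping windows of ``window_s``
    (10 min in the RIS analysis); the correlation is computed within each
    window.  The shuffle control re-pairs behavior windows with randomly
    permuted fluorescence windows ``n_shuffles`` times and returns the
    pooled correlations of the mismatched pairs; the identity permutation
    is allowed unless ``exclude_identity``.  Windows in which either
    series is constant have undefined correlation and are skipped with a
    warning.

    Returns ``(per_window_r, shuffled_r)``.
    """
    behavior = np.asarray(behavior, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    if behavior.size != fluor.size:
        raise ValueError("series must be aligned")
    wlen = int(round(window_s * fps))
    if wlen < 2:
        raise ValueError("window too short")
    n_windows = behavior.size // wlen
    if n_windows < 1:
        raise ValueError("series shorter than one window")
    b_win = behavior[: n_windows * wlen].reshape(n_windows, wlen)
    f_win = fluor[: n_windows * wlen].reshape(n_windows, wlen)

    def safe_r(x: np.ndarray, y: np.ndarray) -> float:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("constant series in window; correlation undefined, skipped")
            return np.nan
        return float(stats.pearsonr(x, y).statistic)

    per_window = np.array([safe_r(b, f) for b, f in zip(b_win, f_win)])
    per_window = per_window[~np.isnan(per_window)]

    shuffled: list[float] = []
    if n_shuffles > 0:
        if n_windows < 2:
            raise ValueError("need >= 2 windows for the shuffle control")
        rng = np.random.default_rng(seed)
        for _ in range(n_shuffles):
            perm = rng.permutation(n_windows)
            if exclude_identity:
                while np.array_equal(perm, np.arange(n_windows)):
                    perm = rng.permutation(n_windows)
            for i, j in enumerate(perm):
                r = safe_r(b_win[i], f_win[j])
                if not np.isnan(r):
                    shuffled.append(r)
    return per_window, np.asarray(shuffled)
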