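"""Synthetic recordings with known ground truth.

Every input the analysis stages consume can be generated here: two-state
(wake/quiescent) activity traces with brief twitches, rendered worm
videos (traveling-wave swimming vs. a frozen high-curvature arc during
quiescence), one- and two-channel fluorescence with photobleaching and a
sleep-active channel, and puncta images with size-bounded bright blobs.
Each generator takes an explicit seed, draws all randomness from a
single ``numpy.random.default_rng`` instance, and returns the ground
truth alongside the data, so detector output can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .posture import dimensionless_curvature_of_points, resample_centerline

__all__ = [
    "BoutSchedule",
    "SyntheticWormConfig",
    "SyntheticTruth",
    "sample_bout_schedule",
    "simulate_activity_trace",
    "render_worm_video",
    "simulate_fluorescence",
    "render_puncta_image",
]


@dataclass
class BoutSchedule:
    """Ground-truth quiescent intervals and twitch times for one recording.

    Intervals are sorted, non-overlapping ``(start_s, end_s)`` pairs in
    ``[0, duration_s)``; every twitch lies inside some interval and lasts
    less than 15 s.
    """

    intervals: list[tuple[float, float]]
    twitches: list[tuple[float, float]]  # (time_s, duration_s)
    duration_s: float

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("schedule intervals overlap or are unsorted")
        for t, d in self.twitches:
            if d >= 15:
                raise ValueError("twitches must last < 15 s")
            if not any(s <= t and t + d <= e for s, e in self.intervals):
                raise ValueError("twitch outside every quiescent interval")

    def total_sleep_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def state_mask(self, n_samples: int, fps: float) -> np.ndarray:
        """True where the animal is quiescent, sampled at ``fps``."""
        t = np.arange(n_samples) / fps
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.intervals:
            mask |= (t >= s) & (t < e)
        return mask

    def twitch_mask(self, n_samples: int, fps: float) -> np.ndarray:
        t = np.arange(n_samples) / fps
        mask = np.zeros(n_samples, dtype=bool)
        for s, d in self.twitches:
            mask |= (t >= s) & (t < s + d)
        return mask


@dataclass
class SyntheticWormConfig:
    """Geometry and rendering parameters for a synthetic worm video."""

    chamber_px: tuple[int, int] = (120, 160)
    worm_length_px: float = 80.0
    worm_width_px: float = 5.0
    fps: float = 3.0
    wake_wave: tuple[float, float, float] = (7.0, 50.0, 0.5)  # (A px, lambda px, f Hz)
    sleep_curvature_gain: float = 1.15
    twitch_rotation_deg: float = 4.0
    brightness: float = 200.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.worm_length_px >= max(self.chamber_px):
            raise ValueError("worm longer than chamber")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    schedule: BoutSchedule | None = None
    centerlines: list[np.ndarray] | None = None
    fluor_truth: dict[str, np.ndarray] | None = None
    puncta_truth: list[tuple[float, float, int]] | None = None  # (row, col, area)


# ---------------------------------------------------------------------------
# Bout schedules
# ---------------------------------------------------------------------------


def sample_bout_schedule(
    duration_s: float,
    mean_sleep_s: float = 240.0,
    mean_wake_s: float = 240.0,
    min_bout_s: float = 30.0,
    twitch_rate_per_min: float = 0.5,
    seed: int | None = None,
    twitch_separation_s: float = 30.0,
) -> BoutSchedule:
    """Sample an alternating wake/sleep schedule.

    Wake durations are exponential with mean ``mean_wake_s``.  Sleep
    durations are exponential with scale ``mean_sleep_s`` truncated below
    at ``min_bout_s`` (equivalently ``min_bout_s + Exp(mean_sleep_s)`` by
    memorylessness), so every generated bout is detectable in principle.
    Twitches arrive as a Poisson process at ``twitch_rate_per_min``
    restricted to sleep intervals, each lasting Uniform[1, 10] s and
    required to fit inside its interval.  Twitches are discrete motor
    events; consecutive ones keep at least ``twitch_separation_s``
    between them so that a cluster of twitches cannot masquerade as a
    sustained wake interruption.  A final sleep interval truncated by the
    recording end is kept only if its observed length is at least
    ``min_bout_s``.
    """
    if duration_s <= 0 or mean_sleep_s <= 0 or mean_wake_s <= 0 or min_bout_s <= 0:
        raise ValueError("all durations must be > 0")
    if min_bout_s > mean_sleep_s + min_bout_s:  # pragma: no cover - tautology guard
        raise ValueError("min_bout_s must not exceed the sleep-duration mean")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[float, float]] = []
    t = 0.0
    while t < duration_s:
        t += rng.exponential(mean_wake_s)
        if t >= duration_s:
            break
        sleep = min_bout_s + rng.exponential(mean_sleep_s)
        end = min(t + sleep, duration_s)
        if end - t >= min_bout_s:
            intervals.append((t, end))
        t += sleep

    twitches: list[tuple[float, float]] = []
    if twitch_rate_per_min > 0:
        rate_s = twitch_rate_per_min / 60.0
        for s, e in intervals:
            tt = s + rng.exponential(1.0 / rate_s)
            while tt < e:
                dur = rng.uniform(1.0, 10.0)
                if tt + dur <= e:
                    twitches.append((tt, dur))
                tt += dur + max(twitch_separation_s, rng.exponential(1.0 / rate_s))
    return BoutSchedule(intervals=intervals, twitches=twitches, duration_s=duration_s)


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------


def simulate_activity_trace(
    schedule: BoutSchedule,
    fps: float = 3.0,
    wake_count: float = 400.0,
    wake_sigma: float = 0.7,
    wake_corr_s: float = 60.0,
    wake_floor: float = 0.5,
    wake_cap: float = 2.5,
    sleep_level: float = 0.02,
    twitch_level: float = 0.35,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Raw (count-like) activity trace realizing a bout schedule.

    Wake activity is a lognormal process, ``wake_count`` times
    ``exp(wake_sigma * g)`` with ``g`` an AR(1) Gaussian with correlation
    time ``wake_corr_s`` — real wake traces fluctuate strongly rather
    than sitting at a plateau — clipped to [``wake_floor``,
    ``wake_cap``] times ``wake_count``: a swimming animal never stops
    flipping pixels, so a wake trace cannot fall to quiescent levels
    without a state change, and the count is physically bounded by the
    ROI size.  The clip range guarantees that normalized wake activity
    stays above every geometry's sleep threshold, so a state change is
    the only way below it.  During
    quiescence the trace drops to ``sleep_level`` of ``wake_count``
    (residual pumping/drift); a twitch raises it to ``twitch_level`` of
    ``wake_count`` for its duration, a sub-locomotion amplitude.  The
    result feeds :func:`wormstate.activity.normalize_activity` like a
    measured raw trace.
    """
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * fps))
    quiet = schedule.state_mask(n, fps)
    twitch = schedule.twitch_mask(n, fps)

    rho = math.exp(-1.0 / (wake_corr_s * fps))
    g = np.empty(n)
    g[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * math.sqrt(1 - rho**2)
    for i in range(1, n):
        g[i] = rho * g[i - 1] + innov[i]
    wake = np.clip(
        wake_count * np.exp(wake_sigma * g - wake_sigma**2 / 2),
        wake_floor * wake_count,
        wake_cap * wake_count,
    )

    trace = np.where(quiet, sleep_level * wake_count, wake)
    trace = np.where(twitch & quiet, twitch_level * wake_count, trace)
    if noise_sd > 0:
        trace = np.clip(trace + rng.normal(0, noise_sd, n), 0, None)
    return trace


# ---------------------------------------------------------------------------
# Worm videos
# ---------------------------------------------------------------------------


def _wake_centerline(config: SyntheticWormConfig, phase: float, n_dense: int = 400) -> np.ndarray:
    """Dense traveling-wave centerline of total arclength worm_length_px."""
    amp, lam, _freq = config.wake_wave
    length = config.worm_length_px
    # oversample in x, then cut at the target arclength
    x = np.linspace(0.0, 1.5 * length, 4 * n_dense)
    y = amp * np.sin(2 * np.pi * x / lam + phase)
    pts = np.column_stack([y, x])  # (row, col)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    keep = s <= length
    pts = pts[keep]
    pts = resample_centerline(pts, n_dense)
    return _center_in_chamber(pts, config.chamber_px)


def _arc_centerline(length: float, turn_angle: float, chamber: tuple[int, int], n_dense: int = 400) -> np.ndarray:
    """Circular arc of given arclength and total turn angle, centered."""
    radius = length / turn_angle
    theta = np.linspace(-turn_angle / 2, turn_angle / 2, n_dense)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return _center_in_chamber(pts, chamber)


def _center_in_chamber(pts: np.ndarray, chamber: tuple[int, int]) -> np.ndarray:
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    offset = (np.asarray(chamber, float) - (hi - lo)) / 2 - lo
    return pts + offset


def _rotate_about_centroid(pts: np.ndarray, angle_rad: float) -> np.ndarray:
    c = pts.mean(axis=0)
    rot = np.array(
        [[math.cos(angle_rad), -math.sin(angle_rad)],
         [math.sin(angle_rad), math.cos(angle_rad)]]
    )
    return (pts - c) @ rot.T + c


def _rasterize_centerline(pts: np.ndarray, config: SyntheticWormConfig) -> np.ndarray:
    """Render a centerline as a bright thick anti-aliased curve.

    The body is the set of pixels within half the worm width of the
    centerline, with a 1-px soft edge, so the rendered worm carries round
    end caps of the cap radius; skeletonization retreats from rounded
    ends by about the same radius, which makes the skeleton length track
    the centerline length.
    """
    h, w = config.chamber_px
    grid = np.ones((h, w), dtype=bool)
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    grid[rows, cols] = False
    dist = ndimage.distance_transform_edt(grid)
    half = config.worm_width_px / 2
    profile = np.clip(half + 0.5 - dist, 0.0, 1.0)  # soft 1-px edge
    return config.background_level + config.brightness * profile


def _solve_arc_turn_angle(length: float, target_dimensionless: float) -> float:
    """Turn angle whose 20-point discretized arc has the target curvature.

    The 20-point pipeline measures chord lengths rather than true
    arclength, so the discrete dimensionless curvature of an arc is
    slightly below its turn angle; invert that mapping numerically.
    """

    def measured(theta: float) -> float:
        radius = length / theta
        t = np.linspace(0, theta, 400)
        dense = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
        return dimensionless_curvature_of_points(resample_centerline(dense))

    lo, hi = 0.05, 1.9 * math.pi
    if not (measured(lo) <= target_dimensionless <= measured(hi)):
        raise ValueError(f"target curvature {target_dimensionless} out of range")
    return float(
        optimize.brentq(lambda th: measured(th) - target_dimensionless, lo, hi, xtol=1e-6)
    )


def render_worm_video(
    config: SyntheticWormConfig, schedule: BoutSchedule
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a worm video realizing a bout schedule.

    During wake the centerline is a traveling sinusoid advancing every
    frame; during quiescent intervals it freezes into a circular arc
    whose dimensionless curvature is ``sleep_curvature_gain`` times the
    mean wake curvature (quiescent animals hold a tighter, hockey-stick-
    like posture).  Twitches briefly rotate the frozen posture.  Returns
    the uint8 stack and the truth (schedule plus one dense centerline per
    frame).
    """
    h, w = config.chamber_px
    if config.worm_length_px > math.hypot(h, w):
        raise ValueError("worm longer than chamber diagonal")
    n_frames = int(round(schedule.duration_s * config.fps))
    if n_frames > 1_000_000:
        raise ValueError("recording too long (> 1e6 frames)")
    rng = np.random.default_rng(config.seed)
    _amp, _lam, freq = config.wake_wave

    # mean wake curvature over a full cycle of phases, by the 20-point measure
    phases = np.linspace(0, 2 * np.pi, 25, endpoint=False)
    wake_mean = float(
        np.mean(
            [
                dimensionless_curvature_of_points(
                    resample_centerline(_wake_centerline(config, p))
                )
                for p in phases
            ]
        )
    )
    theta = _solve_arc_turn_angle(
        config.worm_length_px, config.sleep_curvature_gain * wake_mean
    )
    sleep_pts = _arc_centerline(config.worm_length_px, theta, config.chamber_px)

    quiet = schedule.state_mask(n_frames, config.fps)
    twitch = schedule.twitch_mask(n_frames, config.fps)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    centerlines: list[np.ndarray] = []
    twitch_sign = 1.0
    prev_twitch = False
    for i in range(n_frames):
        t = i / config.fps
        if quiet[i]:
            pts = sleep_pts
            if twitch[i]:
                if not prev_twitch:
                    twitch_sign = -twitch_sign  # alternate twitch direction
                pts = _rotate_about_centroid(
                    sleep_pts, twitch_sign * math.radians(config.twitch_rotation_deg)
                )
            prev_twitch = bool(twitch[i])
        else:
            pts = _wake_centerline(config, -2 * np.pi * freq * t)
            prev_twitch = False
        centerlines.append(pts)
        img = _rasterize_centerline(pts, config)
        if config.noise_sd > 0:
            img = img + rng.normal(0, config.noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, SyntheticTruth(schedule=schedule, centerlines=centerlines)


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------


def simulate_fluorescence(
    schedule: BoutSchedule,
    n_neurons: int = 10,
    fps: float = 5.0,
    bleach_tau_s: float = math.inf,
    ris_like: bool = False,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wake_level: float = 100.0,
    sleep_wake_ratio: float = 0.5,
) -> tuple[dict[str, np.ndarray], SyntheticTruth]:
    """Simulate per-neuron fluorescence with optional sleep-active channel.

    Ordinary neurons emit ``wake_level`` (times a per-neuron scale) in
    wake and ``sleep_wake_ratio`` of it during quiescence; a ``ris_like``
    channel shows the opposite (anti-correlated) pattern, as the
    sleep-active RIS interneuron does.  All green signals and the
    state-independent "red" reference channel decay as
    ``exp(-t / bleach_tau_s)``; Gaussian noise is added last.  Returns
    ``{"neurons": (n_neurons, T), "red": (T,)[, "ris": (T,)]}`` and truth
    holding the noiseless signals plus the quiescence mask.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * fps))
    t = np.arange(n) / fps
    quiet = schedule.state_mask(n, fps)
    bleach = np.exp(-t / bleach_tau_s) if math.isfinite(bleach_tau_s) else np.ones(n)

    scales = wake_level * rng.uniform(0.7, 1.3, size=n_neurons)
    state = np.where(quiet, sleep_wake_ratio, 1.0)
    neurons = scales[:, None] * state[None, :] * bleach[None, :]
    red = wake_level * bleach
    truth_signals: dict[str, np.ndarray] = {
        "neurons": neurons.copy(),
        "red": red.copy(),
        "quiescent": quiet.astype(float),
    }
    out: dict[str, np.ndarray] = {}
    if ris_like:
        ris = wake_level * np.where(quiet, 1.0, sleep_wake_ratio) * bleach
        truth_signals["ris"] = ris.copy()
        out["ris"] = ris + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    out["neurons"] = neurons + (
        rng.normal(0, noise_sd, neurons.shape) if noise_sd else 0.0
    )
    out["red"] = red + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    return out, SyntheticTruth(schedule=schedule, fluor_truth=truth_signals)


# ---------------------------------------------------------------------------
# Puncta images
# ---------------------------------------------------------------------------


def _blob_pixels(center: tuple[int, int], area: int) -> tuple[np.ndarray, np.ndarray]:
    """The ``area`` pixels of a compact blob: nearest-to-center first."""
    r = int(math.ceil(math.sqrt(area / math.pi))) + 2
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dr**2 + dc**2
    # deterministic tie-break: distance, then angle
    order = np.lexsort((np.arctan2(dr, dc).ravel(), d2.ravel()))
    rows = center[0] + dr.ravel()[order][:area]
    cols = center[1] + dc.ravel()[order][:area]
    return rows, cols


def render_puncta_image(
    shape_px: tuple[int, int] = (200, 300),
    n_puncta: int = 5,
    area_range_px: tuple[int, int] = (2, 30),
    background_level: float = 10.0,
    seed: int | None = None,
    body_level: float = 30.0,
    punctum_level: float = 180.0,
    noise_sd: float = 1.0,
    out_of_range_areas: tuple[int, ...] = (),
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a dim worm-body ellipse with bright, non-touching puncta.

    ``n_puncta`` blobs with pixel areas uniform in ``area_range_px`` are
    placed inside the body ellipse with a separation margin so no two
    touch.  ``out_of_range_areas`` blobs (e.g. 1 px and 40 px negative
    controls) are rendered identically but excluded from the truth
    inventory.  Raises on infeasible packing.
    """
    if n_puncta < 0:
        raise ValueError("n_puncta must be >= 0")
    lo, hi = area_range_px
    if not (1 <= lo <= hi):
        raise ValueError("invalid area range")
    rng = np.random.default_rng(seed)
    h, w = shape_px
    img = np.full((h, w), float(background_level))

    cy, cx = h / 2, w / 2
    ay, ax = 0.35 * h, 0.42 * w
    yy, xx = np.mgrid[0:h, 0:w]
    body = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    img[body] += body_level

    areas = list(rng.integers(lo, hi + 1, size=n_puncta)) + list(out_of_range_areas)
    in_range = [True] * n_puncta + [False] * len(out_of_range_areas)
    max_radius = math.ceil(math.sqrt(max(areas, default=1) / math.pi)) + 2
    min_sep = 2 * max_radius + 3
    centers: list[tuple[int, int]] = []
    for _ in areas:
        for attempt in range(10_000):
            r = int(rng.integers(int(cy - ay) + max_radius + 2, int(cy + ay) - max_radius - 1))
            c = int(rng.integers(int(cx - ax) + max_radius + 2, int(cx + ax) - max_radius - 1))
            inside = ((r - cy) / (ay - max_radius - 2)) ** 2 + (
                (c - cx) / (ax - max_radius - 2)
            ) ** 2 <= 1.0
            if inside and all(math.hypot(r - pr, c - pc) >= min_sep for pr, pc in centers):
                centers.append((r, c))
                break
        else:
            raise ValueError("infeasible packing: cannot place non-touching puncta")

    truth: list[tuple[float, float, int]] = []
    for (r, c), area, keep in zip(centers, areas, in_range):
        rows, cols = _blob_pixels((r, c), int(area))
        img[rows, cols] = background_level + body_level + punctum_level
        if keep:
            truth.append((float(rows.mean()), float(cols.mean()), int(area)))
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, None)
    return img, SyntheticTruth(puncta_truth=truth)
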