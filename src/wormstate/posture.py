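"""Worm centerline extraction and dimensionless body curvature.

The posture measure is built from a 20-point centerline: a circle is fit
through every three adjacent points, giving 18 local curvatures (inverse
circumradii, units 1/px); their mean multiplied by the body length in
pixels is a dimensionless curvature that is invariant to image scale.
Swimming animals hold a lower mean curvature than the tightly arced
"hockey-stick" posture adopted during quiescence.

Head and tail are not distinguished: the curvature measure is symmetric
under reversing the point order, so no head detection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure, morphology

from .activity import moving_average
from .sleep import BoutSet

__all__ = [
    "PostureFrame",
    "extract_centerline",
    "circumcurvature",
    "local_curvatures",
    "dimensionless_curvature",
    "dimensionless_curvature_of_points",
    "resample_centerline",
    "mark_valid_frames",
    "curvature_by_state",
]

N_CENTERLINE_POINTS = 20
_COLLINEAR_AREA_TOL = 1e-9  # px^2; triangles flatter than this count as straight


@dataclass
class PostureFrame:
    """Per-frame centerline geometry and curvature."""

    frame_index: int
    centerline: np.ndarray | None  # (20, 2) (row, col), equally spaced in arclength
    body_length_px: float
    local_curvatures: np.ndarray | None  # 18 values, 1/px
    mean_dimensionless_curvature: float | None
    valid: bool


def circumcurvature(p1, p2, p3) -> float:
    """Curvature 1/R of the circle through three points.

    R = abc / 4K with a, b, c the triangle side lengths and K its area.
    Collinear points (area below a small tolerance) give curvature 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    if min(a, b, c) == 0.0:
        raise ValueError("coincident points have no circumcircle")
    # signed cross product = 2K
    v1, v2 = p2 - p1, p3 - p1
    area = 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0])
    if area < _COLLINEAR_AREA_TOL:
        return 0.0
    return float(4.0 * area / (a * b * c))


def local_curvatures(centerline: np.ndarray) -> np.ndarray:
    """Curvatures of circles through each window of three adjacent points."""
    pts = np.asarray(centerline, dtype=float)
    return np.array(
        [circumcurvature(pts[i], pts[i + 1], pts[i + 2]) for i in range(len(pts) - 2)]
    )


def _arclength(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def resample_centerline(points: np.ndarray, n_points: int = N_CENTERLINE_POINTS) -> np.ndarray:
    """Resample an ordered polyline to ``n_points`` equally spaced in arclength."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] == 0:
        raise ValueError("degenerate centerline (zero length)")
    target = np.linspace(0.0, s[-1], n_points)
    return np.column_stack(
        [np.interp(target, s, points[:, 0]), np.interp(target, s, points[:, 1])]
    )


def dimensionless_curvature_of_points(centerline: np.ndarray) -> float:
    """Mean of the 18 local curvatures times the body length (dimensionless)."""
    pts = np.asarray(centerline, dtype=float)
    return float(np.mean(local_curvatures(pts)) * _arclength(pts))


def dimensionless_curvature(posture: PostureFrame) -> float | None:
    """Dimensionless curvature of a posture frame; None if the frame is invalid."""
    if not posture.valid or posture.local_curvatures is None:
        return None
    return float(np.mean(posture.local_curvatures) * posture.body_length_px)


# ---------------------------------------------------------------------------
# Centerline extraction from images
# ---------------------------------------------------------------------------


def _skeleton_longest_path(skeleton: np.ndarray) -> np.ndarray | None:
    """Maximal-geodesic endpoint-to-endpoint pixel path through a skeleton.

    The skeleton may retain short spurious branches; the path between the
    two most geodesically distant endpoints traces the worm's body axis.
    """
    coords = np.argwhere(skeleton)
    if coords.size == 0:
        return None
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    nbrs: list[list[int]] = [[] for _ in coords]
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for (r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def bfs(src: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(coords), -1, dtype=int)
        prev = np.full(len(coords), -1, dtype=int)
        dist[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in nbrs[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        prev[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, prev

    endpoints = [i for i, nb in enumerate(nbrs) if len(nb) <= 1]
    if not endpoints:  # closed loop (self-coiled worm): pick any pixel
        endpoints = [0]
    # double-sweep: farthest node from an arbitrary endpoint, then farthest
    # from that; exact on trees, good approximation on near-trees
    d0, _ = bfs(endpoints[0])
    reachable = d0 >= 0
    a = int(np.argmax(np.where(reachable, d0, -1)))
    d1, prev = bfs(a)
    b = int(np.argmax(np.where(d1 >= 0, d1, -1)))
    path = []
    node = b
    while node != -1:
        path.append(node)
        node = int(prev[node]) if node != a else -1
    return coords[path[::-1]]


def _smooth_path(path: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of pixel-path coordinates.

    Skeleton paths carry +/- half-pixel jitter; a circle through three
    nearby jittered points badly overestimates curvature, so the path is
    smoothed before arclength resampling.  Endpoints use a shrinking
    window so the path ends are not pulled inward.
    """
    if len(path) <= window:
        return path
    kernel = np.ones(window)
    num_r = np.convolve(path[:, 0], kernel, mode="same")
    num_c = np.convolve(path[:, 1], kernel, mode="same")
    den = np.convolve(np.ones(len(path)), kernel, mode="same")
    return np.column_stack([num_r / den, num_c / den])


def extract_centerline(
    frame: np.ndarray,
    background: np.ndarray,
    frame_index: int = 0,
    min_object_px: int = 30,
    smooth_sigma: float = 1.0,
) -> PostureFrame:
    """Segment the worm in one frame and fit the 20-point centerline.

    The background image (chamber with no animal) is subtracted, contrast
    is stretched, the frame is thresholded (Otsu), small objects removed,
    the mask Gaussian-smoothed and re-thresholded, then skeletonized.  The
    longest skeleton path is jitter-smoothed and resampled to 20 points
    equally spaced in arclength.  Frames with no foreground object are
    marked invalid.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")

    invalid = PostureFrame(frame_index, None, 0.0, None, None, valid=False)

    sub = np.clip(frame - background, 0, None)
    if sub.max() <= 0:
        return invalid
    adj = exposure.rescale_intensity(sub, out_range=(0.0, 1.0))
    try:
        thr = filters.threshold_otsu(adj)
    except ValueError:
        return invalid
    binary = adj > thr
    binary = morphology.remove_small_objects(binary, max_size=min_object_px - 1)
    if not binary.any():
        return invalid
    smoothed = ndimage.gaussian_filter(binary.astype(float), smooth_sigma) > 0.5
    if not smoothed.any():
        smoothed = binary
    # keep the largest connected component (the worm body)
    labels = measure.label(smoothed)
    if labels.max() == 0:
        return invalid
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    body = labels == largest
    skeleton = morphology.skeletonize(body)
    path = _skeleton_longest_path(skeleton)
    if path is None or len(path) < 3:
        return invalid
    path = _smooth_path(path.astype(float))
    centerline = resample_centerline(path, N_CENTERLINE_POINTS)
    length = _arclength(centerline)
    curv = local_curvatures(centerline)
    return PostureFrame(
        frame_index=frame_index,
        centerline=centerline,
        body_length_px=length,
        local_curvatures=curv,
        mean_dimensionless_curvature=float(np.mean(curv) * length),
        valid=True,
    )


def mark_valid_frames(
    postures: list[PostureFrame],
    min_length_fraction: float = 0.8,
    running: bool = False,
) -> list[PostureFrame]:
    """Apply the body-length quality gate in place and return the list.

    Frames whose body length falls below ``min_length_fraction`` of the
    animal's average length (self-coiled postures foreshorten the
    skeleton) are marked invalid.  The reference is the mean length over
    all segmentable frames by default, or a running mean over the frames
    processed so far when ``running`` is true.
    """
    lengths = [p.body_length_px for p in postures if p.valid]
    if not lengths:
        return postures
    if running:
        seen: list[float] = []
        for p in postures:
            if not p.valid:
                continue
            seen.append(p.body_length_px)
            if p.body_length_px < min_length_fraction * float(np.mean(seen)):
                p.valid = False
    else:
        mean_len = float(np.mean(lengths))
        for p in postures:
            if p.valid and p.body_length_px < min_length_fraction * mean_len:
                p.valid = False
    return postures


def curvature_by_state(
    curvatures: np.ndarray,
    bouts: BoutSet,
    fps: float,
    smooth_s: float = 20.0,
) -> tuple[float | None, float | None]:
    """Mean dimensionless curvature during wake and during sleep.

    ``curvatures`` is the per-frame dimensionless value with NaN for
    invalid frames; the series is smoothed over ``smooth_s`` (NaN-aware)
    and averaged separately over frames inside and outside sleep bouts.
    A state with no valid frames yields None.
    """
    curv = np.asarray(curvatures, dtype=float)
    valid = ~np.isnan(curv)
    window = int(round(smooth_s * fps))
    if window > 1:
        filled = np.where(valid, curv, 0.0)
        num = moving_average(filled, window)
        den = moving_average(valid.astype(float), window)
        with np.errstate(invalid="ignore", divide="ignore"):
            curv = np.where(den > 0, num / den, np.nan)
    in_sleep = bouts.in_bout_mask(curv.size, fps)

    def state_mean(mask: np.ndarray) -> float | None:
        sel = mask & valid
        return float(np.nanmean(curv[sel])) if sel.any() else None

    return state_mean(~in_sleep), state_mean(in_sleep)
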