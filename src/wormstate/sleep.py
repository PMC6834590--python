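"""Quiescent-bout detection and bout statistics.

A sleep bout is a period in which normalized activity stays below a
chamber-geometry-specific threshold.  Two rules clean up raw threshold
crossings: brief twitches (supra-threshold interruptions shorter than
15 s) do not terminate a bout, and bouts shorter than a 30 s minimum are
discarded as false detections.  Merging runs before applying the minimum
is the only order under which a long bout interrupted by a single twitch
survives the minimum-length filter as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoutSet",
    "BoutStatistics",
    "detect_bouts",
    "bout_statistics",
    "geometry_threshold",
    "GEOMETRY_THRESHOLDS",
]

# Quiescence thresholds on normalized activity, per chamber geometry.
# Larger chambers allow drift during sleep, so their thresholds are looser;
# the RIS imaging rig uses its own value.
GEOMETRY_THRESHOLDS: dict[str, float] = {
    "wormotel": 0.15,
    "chamber_500um": 0.15,
    "chamber_110um": 0.08,
    "chamber_50um": 0.06,
    "ris_50um": 0.2,
}


def geometry_threshold(geometry: str) -> float:
    """Sleep-detection threshold for a chamber geometry label."""
    try:
        return GEOMETRY_THRESHOLDS[geometry]
    except KeyError:
        raise ValueError(
            f"unknown geometry {geometry!r}; valid labels: "
            f"{sorted(GEOMETRY_THRESHOLDS)}"
        ) from None


@dataclass
class BoutSet:
    """Ordered quiescent intervals for one animal.

    Bouts are half-open ``[start_s, end_s)`` intervals in seconds at frame
    resolution, sorted and non-overlapping; gaps between consecutive bouts
    are at least ``max_twitch_s`` (anything shorter was merged away).
    """

    animal_id: str
    bouts: list[tuple[float, float]]
    threshold: float
    min_bout_s: float
    max_twitch_s: float
    recording_s: float

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.bouts, self.bouts[1:]):
            if s1 < e0:
                raise ValueError("bouts overlap or are unsorted")

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def in_bout_mask(self, n_samples: int, fps: float) -> np.ndarray:
        """Boolean mask over a time base of ``n_samples`` at ``fps``."""
        t = np.arange(n_samples) / fps
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.bouts:
            mask |= (t >= s) & (t < e)
        return mask


@dataclass
class BoutStatistics:
    total_sleep_s: float
    sleep_fraction: float
    onset_s: float | None
    sleep_bout_lengths_s: list[float]
    wake_bout_lengths_s: list[float]  # excludes the pre-first-bout wake period
    homeostasis_pairs: list[tuple[float, float]]  # (preceding wake, sleep bout)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_bouts(
    normalized: np.ndarray,
    fps: float,
    threshold: float,
    min_bout_s: float = 30.0,
    max_twitch_s: float = 15.0,
    animal_id: str = "",
) -> BoutSet:
    """Detect quiescent bouts in a normalized activity series.

    Frames with ``activity < threshold`` (strict) are candidate-quiescent.
    Runs of candidates separated by supra-threshold gaps strictly shorter
    than ``max_twitch_s`` are merged, then merged runs shorter than
    ``min_bout_s`` are discarded.  A bout truncated by the end of the
    recording is kept if its observed length passes the minimum.
    """
    normalized = np.asarray(normalized, dtype=float)
    if fps <= 0 or threshold <= 0 or min_bout_s <= 0 or max_twitch_s < 0:
        raise ValueError("fps, threshold, min_bout_s must be > 0; max_twitch_s >= 0")
    if normalized.size == 0:
        return BoutSet(animal_id, [], threshold, min_bout_s, max_twitch_s, 0.0)
    if np.isnan(normalized).any():
        raise ValueError("activity series contains NaN")

    quiet = normalized < threshold
    runs = _runs(quiet)

    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) / fps < max_twitch_s:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    bouts = [
        (start / fps, stop / fps)
        for start, stop in merged
        if (stop - start) / fps >= min_bout_s
    ]
    return BoutSet(
        animal_id=animal_id,
        bouts=bouts,
        threshold=threshold,
        min_bout_s=min_bout_s,
        max_twitch_s=max_twitch_s,
        recording_s=normalized.size / fps,
    )


def bout_statistics(bout_set: BoutSet) -> BoutStatistics:
    """Summary statistics over a bout set.

    Wake bouts are the gaps between consecutive sleep bouts plus the gap
    from the last bout to the end of the recording; the period before the
    first bout is excluded.  Each sleep bout after the first is paired with
    the wake bout immediately preceding it (the homeostasis pairing used to
    relate prior wake time to subsequent sleep).
    """
    bouts = bout_set.bouts
    lengths = [e - s for s, e in bouts]
    total = float(sum(lengths))
    rec = bout_set.recording_s
    fraction = total / rec if rec > 0 else 0.0

    wake_lengths: list[float] = []
    pairs: list[tuple[float, float]] = []
    for (s0, e0), (s1, e1) in zip(bouts, bouts[1:]):
        wake = s1 - e0
        wake_lengths.append(wake)
        pairs.append((wake, e1 - s1))
    if bouts and rec > bouts[-1][1]:
        wake_lengths.append(rec - bouts[-1][1])

    return BoutStatistics(
        total_sleep_s=total,
        sleep_fraction=fraction,
        onset_s=bouts[0][0] if bouts else None,
        sleep_bout_lengths_s=lengths,
        wake_bout_lengths_s=wake_lengths,
        homeostasis_pairs=pairs,
    )
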