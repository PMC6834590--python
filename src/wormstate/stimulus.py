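"""Stimulus-response quantification and resampling statistics.

Around each stimulus (a 0.5-s valve pulse, or a light flash), the animal's
behavioral state is classified from its mean normalized activity in the
10 s before the stimulus: quiescent below 0.08, low-activity wake in
[0.08, 0.35], high-activity wake above 0.35.  The response is the mean
activity in the 10 s after the stimulus, excluding the first 2 s in which
valve actuation itself moves the animal.  Group-level responsiveness
(fraction of trials ending awake) carries a bootstrap standard deviation,
and group differences are tested by label permutation with a Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusTrial",
    "classify_pre_state",
    "post_response",
    "fraction_awake",
    "resampling_test",
    "SLEEP_UPPER",
    "LOW_WAKE_UPPER",
]

SLEEP_UPPER = 0.08  # activity below this before the stimulus: quiescent
LOW_WAKE_UPPER = 0.35  # [0.08, 0.35]: low-activity wake; above: high-activity


class TrialExcludedError(ValueError):
    """Raised when a trial's analysis window falls outside the recording."""


@dataclass
class StimulusTrial:
    animal_id: str
    stim_time_s: float
    stim_kind: str  # light | mech_strong | mech_weak
    pre_window_s: float = 10.0
    post_window_s: float = 10.0
    artifact_s: float = 2.0
    pre_state: str | None = None
    pre_mean: float | None = None
    post_mean: float | None = None


def _window_mean(series: np.ndarray, fps: float, t0: float, t1: float) -> float:
    """Mean over samples with t0 <= index/fps < t1."""
    i0 = int(np.ceil(t0 * fps - 1e-9))
    i1 = int(np.ceil(t1 * fps - 1e-9))
    if i0 < 0 or i1 > series.size or i1 <= i0:
        raise TrialExcludedError(
            f"window [{t0}, {t1}) s outside recording of {series.size / fps} s"
        )
    return float(series[i0:i1].mean())


def classify_pre_state(
    normalized: np.ndarray,
    stim_time_s: float,
    pre_window_s: float = 10.0,
    fps: float = 3.0,
) -> tuple[str, float]:
    """Classify the pre-stimulus state from mean activity before the stimulus.

    Returns ``(label, pre_mean)`` with label one of ``sleep`` (< 0.08),
    ``low_wake`` ([0.08, 0.35], boundaries inclusive) or ``high_wake``.
    """
    normalized = np.asarray(normalized, dtype=float)
    pre = _window_mean(normalized, fps, stim_time_s - pre_window_s, stim_time_s)
    if pre < SLEEP_UPPER:
        return "sleep", pre
    if pre <= LOW_WAKE_UPPER:
        return "low_wake", pre
    return "high_wake", pre


def post_response(
    normalized: np.ndarray,
    stim_time_s: float,
    post_window_s: float = 10.0,
    artifact_s: float = 2.0,
    fps: float = 3.0,
) -> float:
    """Mean activity over (stim + artifact, stim + post_window].

    The first ``artifact_s`` seconds are excluded because valve actuation
    displaces the animal regardless of its state; light-stimulus analyses
    pass ``artifact_s=0``.
    """
    if artifact_s >= post_window_s:
        raise ValueError("artifact_s must be shorter than post_window_s")
    normalized = np.asarray(normalized, dtype=float)
    # window open on the left (artifact excluded), closed on the right
    t0 = stim_time_s + artifact_s
    t1 = stim_time_s + post_window_s
    i0 = int(np.floor(t0 * fps + 1e-9)) + 1
    i1 = int(np.floor(t1 * fps + 1e-9)) + 1
    if i0 < 0 or i1 > normalized.size or i1 <= i0:
        raise TrialExcludedError(
            f"window ({t0}, {t1}] s outside recording of {normalized.size / fps} s"
        )
    return float(normalized[i0:i1].mean())


def fraction_awake(
    trials: list[StimulusTrial] | np.ndarray,
    wake_threshold: float = 0.06,
    n_boot: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fraction of trials whose post-stimulus activity exceeds the threshold.

    A trial counts as awake if ``post_mean > wake_threshold`` (by default
    the 50-um-chamber sleep threshold).  The uncertainty is the standard
    deviation of the fraction over ``n_boot`` bootstrap resamples of the
    trials (resampling with replacement).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(trials, np.ndarray) or (trials and not isinstance(trials[0], StimulusTrial)):
        outcomes = np.asarray(trials, dtype=float) > wake_threshold
    else:
        outcomes = np.array([t.post_mean > wake_threshold for t in trials])
    n = outcomes.size
    if n == 0:
        raise ValueError("no trials")
    frac = float(outcomes.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = outcomes[idx].mean(axis=1)
    return frac, float(boot.std())


def resampling_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_iter: int = 5000,
    n_comparisons: int = 1,
    seed: int | None = None,
) -> float:
    """Permutation test on the difference in group fractions.

    Outcomes are pooled, group labels reassigned at random preserving the
    group sizes, and the two-sided Monte-Carlo p-value uses the add-one
    estimator p = (1 + #{|d*| >= |d_obs|}) / (1 + n_iter) so it can never
    be zero.  The Bonferroni-adjusted value (multiplied by
    ``n_comparisons``, capped at 1) is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pooled = np.concatenate([a, b])
    n_a = a.size
    d_obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    # vectorized label permutations: argsort of uniform noise per row
    order = np.argsort(rng.random((n_iter, pooled.size)), axis=1)
    perm = pooled[order]
    d_star = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
    p = (1 + int(np.count_nonzero(d_star >= d_obs - 1e-12))) / (1 + n_iter)
    return min(1.0, p * n_comparisons)
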