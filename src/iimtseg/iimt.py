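"""Interval-iteration multilevel thresholding (IIMT).

Standard multilevel Otsu searches the whole histogram at once and is pulled
toward classes with large variance.  IIMT instead refines each threshold
inside a shrinking gray-level interval:

1. A global multilevel Otsu run yields K initial thresholds and the K+1
   class means ``mu_1 <= ... <= mu_{K+1}``.
2. Each threshold i is re-estimated by single-threshold Otsu restricted to
   the interval ``[mu_i, mu_{i+1}]``; the two within-interval class means
   become the next (nested) interval.
3. A threshold is frozen once it moves by less than ``delta`` between
   consecutive iterations (with integer thresholds and the default
   ``delta = 0.01`` this is exact equality), or once its interval becomes
   degenerate.  Iteration stops when every threshold is frozen.

The K refinement tracks are independent after the first iteration; because
class means of a sub-interval lie inside it, the intervals are nested and
the integer thresholds must eventually repeat, so the loop terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .otsu import (
    GrayHistogram,
    class_stats,
    otsu_multilevel,
    otsu_single_in_interval,
)

__all__ = [
    "IimtConfig",
    "ThresholdTrack",
    "IntervalState",
    "InternalConsistencyError",
    "iimt_first_iteration",
    "iimt_refine",
    "iimt_thresholds",
    "apply_thresholds",
]


class InternalConsistencyError(RuntimeError):
    """Final thresholds violate strict monotonicity."""


@dataclass
class IimtConfig:
    """Parameters of the interval-iteration search.

    k : number of thresholds (K >= 1; K+1 classes).
    delta : stopping constant; a threshold is frozen when it moves by less
        than delta between consecutive iterations (default 0.01, i.e.
        integer thresholds freeze on exact repetition).
    max_iterations : safety cap on the number of iterations; with
        ``max_iterations = 1`` the search reduces to global multilevel Otsu.
    """

    k: int
    delta: float = 0.01
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ThresholdTrack:
    """Refinement state of one threshold."""

    lower: float
    upper: float
    threshold: int
    previous: int | None = None
    converged: bool = False
    history: list[int] = field(default_factory=list)


@dataclass
class IntervalState:
    """State of all K refinement tracks after iteration ``iteration``."""

    tracks: list[ThresholdTrack]
    iteration: int

    @property
    def converged(self) -> bool:
        return all(t.converged for t in self.tracks)

    def thresholds(self) -> np.ndarray:
        return np.asarray([t.threshold for t in self.tracks], dtype=np.int64)


def iimt_first_iteration(hist: GrayHistogram, k: int) -> IntervalState:
    """Global Otsu initialization: K thresholds and K nested-search intervals.

    Track i starts with interval ``[mu_i, mu_{i+1}]`` (adjacent class means
    of the global Otsu partition) and the global threshold ``T_i``.
    """
    thresholds = otsu_multilevel(hist, k)
    means = class_stats(hist, thresholds).means
    tracks = [
        ThresholdTrack(
            lower=float(means[i]),
            upper=float(means[i + 1]),
            threshold=int(thresholds[i]),
            history=[int(thresholds[i])],
        )
        for i in range(k)
    ]
    return IntervalState(tracks=tracks, iteration=1)


def iimt_refine(hist: GrayHistogram, state: IntervalState, delta: float) -> IntervalState:
    """One refinement sweep: re-run interval Otsu on every unconverged track.

    Each track's new interval is bounded by the two within-interval class
    means (hence nested in the old interval); a track freezes when its
    threshold moves by less than ``delta`` or its interval is degenerate.
    Converged tracks are left untouched, and a track that converges keeps
    the interval its final threshold was computed from, so every final
    threshold is reproducible by re-running the within-interval Otsu step
    on the track's stored interval.
    """
    for track in state.tracks:
        if track.converged:
            continue
        t, mean_low, mean_high, degenerate = otsu_single_in_interval(
            hist, track.lower, track.upper
        )
        track.previous = track.threshold
        track.threshold = t
        track.history.append(t)
        track.converged = degenerate or abs(t - track.previous) < delta
        if not track.converged:
            track.lower = mean_low
            track.upper = mean_high
    state.iteration += 1
    return state


def iimt_thresholds(hist: GrayHistogram, config: IimtConfig) -> np.ndarray:
    """Run IIMT to convergence and return the final K thresholds."""
    return run_iimt(hist, config)[0]


def run_iimt(hist: GrayHistogram, config: IimtConfig) -> tuple[np.ndarray, IntervalState]:
    """Like :func:`iimt_thresholds` but also return the final state (trace)."""
    state = iimt_first_iteration(hist, config.k)
    while state.iteration < config.max_iterations and not state.converged:
        iimt_refine(hist, state, config.delta)
    thresholds = state.thresholds()
    if np.any(np.diff(thresholds) <= 0):
        raise InternalConsistencyError(
            f"thresholds not strictly increasing: {thresholds.tolist()}"
        )
    return thresholds, state


def apply_thresholds(image: np.ndarray, thresholds) -> np.ndarray:
    """Rasterize thresholds into a 0-based label map.

    Pixel with gray value g gets label i where ``t_i < g <= t_{i+1}``
    (with t_0 = -1, t_{K+1} = 255); i.e. a pixel equal to a threshold
    belongs to the class below it.
    """
    t = np.asarray(thresholds, dtype=np.int64).ravel()
    return np.searchsorted(t, np.asarray(image), side="left").astype(np.int64)
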