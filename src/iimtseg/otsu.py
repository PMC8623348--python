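"""Histogram construction and multilevel Otsu thresholding.

The Otsu criterion partitions the 256 gray levels of an 8-bit image into
K+1 contiguous classes by K integer thresholds and scores a candidate
threshold tuple by the between-class variance

    sigma_B^2(t_1, ..., t_K) = sum_i  w_i * (mu_i - mu_T)^2,

where ``w_i`` and ``mu_i`` are the probability mass and mean gray level of
class ``C_i`` and ``mu_T`` is the global mean.  Maximizing sigma_B^2 is
equivalent to minimizing the within-class variance (law of total variance),
which makes the exact optimum the intensity-contiguous k-means partition of
the histogram.

The search here is an exact dynamic program over cumulative histogram sums:
each class contributes ``s^2 / w`` (with ``s`` the first-moment mass) to
``sum_i w_i mu_i^2 = sigma_B^2 + mu_T^2``, so the optimal tuple maximizes a
sum of per-segment scores.  Forward greedy reconstruction with first-argmax
tie-breaking returns the lexicographically smallest maximizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrayHistogram",
    "ClassStats",
    "InfeasibleKError",
    "InvalidImageError",
    "InvalidIntervalError",
    "compute_histogram",
    "class_stats",
    "between_class_variance",
    "otsu_multilevel",
    "otsu_single_in_interval",
]

N_LEVELS = 256


class InvalidImageError(ValueError):
    """Pixel values are not integers in [0, 255]."""


class InfeasibleKError(ValueError):
    """Histogram has fewer than K+1 occupied bins."""


class InvalidIntervalError(ValueError):
    """Interval lower bound exceeds upper bound."""


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin gray-level histogram of an 8-bit image.

    Attributes
    ----------
    counts : ndarray of int, shape (256,)
        Number of pixels at each gray level.
    probabilities : ndarray of float, shape (256,)
        ``counts / total_pixels``; sums to 1.
    total_pixels : int
        Number of pixels in the source image.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    total_pixels: int

    @property
    def occupied_bins(self) -> np.ndarray:
        """Gray levels with at least one pixel."""
        return np.flatnonzero(self.counts > 0)

    @classmethod
    def from_probabilities(cls, probabilities: np.ndarray) -> "GrayHistogram":
        """Build a histogram from an arbitrary non-negative 256-vector.

        The vector is renormalized to sum to 1; counts are synthesized from a
        nominal pixel total so the invariant ``P_j = n_j / total`` holds only
        approximately for non-integer inputs (used for restricted/renormalized
        histograms and random test corpora).
        """
        p = np.asarray(probabilities, dtype=float)
        if p.shape != (N_LEVELS,) or np.any(p < 0):
            raise ValueError("probabilities must be a non-negative 256-vector")
        total = p.sum()
        if total <= 0:
            raise ValueError("probabilities must have positive mass")
        p = p / total
        scale = 10**9
        counts = np.round(p * scale).astype(np.int64)
        return cls(counts=counts, probabilities=p, total_pixels=scale)


@dataclass(frozen=True)
class ClassStats:
    """Per-class probability masses and means for a threshold tuple.

    ``weights`` and ``means`` have length K+1; ``total_mean`` is the mean
    gray level of the whole histogram.  A class with zero probability mass
    has its mean defined as 0 and contributes nothing to sigma_B^2.
    """

    weights: np.ndarray
    means: np.ndarray
    total_mean: float


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidImageError("image must be a non-empty 2-D array")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.mod(arr, 1) == 0):
            raise InvalidImageError("pixel values must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidImageError("pixel values must lie in [0, 255]")
    return arr


def compute_histogram(image: np.ndarray) -> GrayHistogram:
    """Count pixels per gray level and normalize to probabilities."""
    arr = _validate_image(image)
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=N_LEVELS)
    total = int(arr.size)
    return GrayHistogram(
        counts=counts, probabilities=counts / total, total_pixels=total
    )


def _validate_thresholds(thresholds) -> np.ndarray:
    t = np.asarray(thresholds, dtype=np.int64).ravel()
    if t.size < 1:
        raise ValueError("at least one threshold required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if t[0] < 0 or t[-1] > 254:
        raise ValueError("thresholds must lie in [0, 254]")
    return t


def class_stats(hist: GrayHistogram, thresholds) -> ClassStats:
    """Class probabilities and means for a threshold tuple.

    Class i (1-based) covers gray levels ``t_{i-1}+1 ... t_i`` with
    ``t_0 = -1`` and ``t_{K+1} = 255``; a zero-mass class gets mean 0.
    """
    t = _validate_thresholds(thresholds)
    p = hist.probabilities
    levels = np.arange(N_LEVELS, dtype=float)
    edges = np.concatenate(([0], t + 1, [N_LEVELS]))
    weights = np.add.reduceat(p, edges[:-1])
    firsts = np.add.reduceat(levels * p, edges[:-1])
    means = np.divide(firsts, weights, out=np.zeros_like(firsts), where=weights > 0)
    total_mean = float(levels @ p)
    return ClassStats(weights=weights, means=means, total_mean=total_mean)


def between_class_variance(hist: GrayHistogram, thresholds) -> float:
    """Between-class variance sigma_B^2 of a threshold tuple."""
    st = class_stats(hist, thresholds)
    return float(st.weights @ (st.means - st.total_mean) ** 2)


def _segment_scores(p: np.ndarray) -> np.ndarray:
    """Matrix S[a, b] = s(a,b)^2 / w(a,b) for bin ranges a..b (0 if empty)."""
    cw = np.concatenate(([0.0], np.cumsum(p)))
    cs = np.concatenate(([0.0], np.cumsum(np.arange(N_LEVELS) * p)))
    w = cw[None, 1:] - cw[:-1, None]  # w[a, b] for a <= b (garbage for a > b)
    s = cs[None, 1:] - cs[:-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    return np.triu(score)


def otsu_multilevel(hist: GrayHistogram, k: int) -> np.ndarray:
    """Globally optimal K thresholds maximizing the between-class variance.

    Exact dynamic program over all strictly increasing integer K-tuples in
    [0, 254]; among tied maximizers the lexicographically smallest tuple is
    returned.  Raises :class:`InfeasibleKError` if the histogram has fewer
    than K+1 occupied bins.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hist.occupied_bins.size < k + 1:
        raise InfeasibleKError(
            f"need at least {k + 1} occupied bins for K={k}, "
            f"got {hist.occupied_bins.size}"
        )
    p = hist.probabilities
    score = _segment_scores(p)

    n_classes = k + 1
    # h[a] = best total score of the current number of trailing segments
    # covering bins a..255.  Built backward from 1 segment up to K+1.
    h = score[:, N_LEVELS - 1].copy()  # one segment a..255
    tables = [h]
    for seg in range(2, n_classes + 1):
        h_prev = tables[-1]
        h_new = np.full(N_LEVELS, -np.inf)
        # first segment starts at a, ends at b; remaining seg-1 segments
        # need b <= 255 - (seg - 1)
        b_hi = N_LEVELS - seg + 1  # exclusive bound on b
        for a in range(0, b_hi):
            vals = score[a, a:b_hi] + h_prev[a + 1 : b_hi + 1]
            h_new[a] = vals.max()
        tables.append(h_new)

    # Forward greedy reconstruction: at each step pick the smallest segment
    # end attaining the optimum (np.argmax returns the first maximizer).
    thresholds = []
    a = 0
    for remaining in range(n_classes, 1, -1):
        h_prev = tables[remaining - 2]
        b_hi = N_LEVELS - remaining + 1
        vals = score[a, a:b_hi] + h_prev[a + 1 : b_hi + 1]
        b = a + int(np.argmax(vals))
        thresholds.append(b)
        a = b + 1
    return np.asarray(thresholds, dtype=np.int64)


def otsu_single_in_interval(
    hist: GrayHistogram, lo: float, hi: float
) -> tuple[int, float, float, bool]:
    """Single-threshold Otsu restricted to gray levels in [lo, hi].

    The histogram is restricted to integer gray levels ``g`` with
    ``lo <= g <= hi`` (inclusive real bounds), renormalized, and searched
    with K=1.  Returns ``(threshold, mean_low, mean_high, degenerate)``
    where the means are the two class means within the interval.

    If the restricted support has fewer than 2 occupied bins the result is
    degenerate: ``threshold = floor((lo + hi) / 2)`` and the means are the
    interval endpoints.
    """
    if lo > hi:
        raise InvalidIntervalError(f"invalid interval [{lo}, {hi}]")
    lo = max(0.0, float(lo))
    hi = min(255.0, float(hi))
    g_lo = int(math.ceil(lo))
    g_hi = int(math.floor(hi))
    restricted = np.zeros(N_LEVELS)
    if g_lo <= g_hi:
        restricted[g_lo : g_hi + 1] = hist.probabilities[g_lo : g_hi + 1]
    if np.count_nonzero(restricted) < 2:
        return int(math.floor((lo + hi) / 2)), float(lo), float(hi), True
    sub = GrayHistogram.from_probabilities(restricted)
    t = int(otsu_multilevel(sub, 1)[0])
    st = class_stats(sub, [t])
    return t, float(st.means[0]), float(st.means[1]), False
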