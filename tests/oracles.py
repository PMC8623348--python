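"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's prefix-sum/DP machinery: scores are
computed by direct summation over gray-level slices, and searches by
explicit enumeration of candidate tuples.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def sigma_b_direct(p: np.ndarray, thresholds) -> float:
    """Between-class variance by direct per-class summation."""
    levels = np.arange(256, dtype=float)
    mu_t = float(np.sum(levels * p))
    edges = [-1] + list(thresholds) + [255]
    total = 0.0
    for i in range(len(edges) - 1):
        lo, hi = edges[i] + 1, edges[i + 1]
        w = float(np.sum(p[lo : hi + 1]))
        if w > 0:
            mu = float(np.sum(levels[lo : hi + 1] * p[lo : hi + 1])) / w
            total += w * (mu - mu_t) ** 2
    return total


def otsu_exhaustive_full_range(p: np.ndarray, k: int) -> tuple:
    """Enumerate every strictly increasing integer K-tuple in [0, 254].

    Returns the lexicographically smallest maximizer.  Only practical for
    K <= 2 (or narrow searches); used for tie-break fixtures.
    """
    best, best_t = -1.0, None
    for t in itertools.combinations(range(255), k):
        v = sigma_b_direct(p, t)
        if v > best:
            best, best_t = v, t
    return best_t


@lru_cache(maxsize=None)
def _combo_indices(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.int64)


def otsu_exhaustive_occupied(p: np.ndarray, k: int) -> tuple:
    """Exhaustive search over tuples of occupied gray levels.

    For a histogram with strictly positive random masses the global optimum
    has every class non-empty, and the lexicographically smallest maximizer
    places each threshold at the last occupied bin of its class, so
    enumerating occupied-bin tuples is exhaustive for generic inputs.
    Vectorized so large corpora stay fast.
    """
    occ = np.flatnonzero(p > 0)
    cand = occ[occ <= 254]
    combos = cand[_combo_indices(len(cand), k)]
    # drop tuples whose top class would be empty
    combos = combos[combos[:, -1] < occ.max()]
    cw = np.concatenate(([0.0], np.cumsum(p)))
    cs = np.concatenate(([0.0], np.cumsum(np.arange(256) * p)))
    edges = np.hstack(
        [np.zeros((len(combos), 1), dtype=np.int64), combos + 1,
         np.full((len(combos), 1), 256)]
    )
    w = cw[edges[:, 1:]] - cw[edges[:, :-1]]
    s = cs[edges[:, 1:]] - cs[edges[:, :-1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0).sum(axis=1)
    ties = np.flatnonzero(scores == scores.max())
    rows = combos[ties]
    order = np.lexsort(rows.T[::-1])
    return tuple(int(x) for x in rows[order[0]])


def hausdorff_double_loop(a, b) -> float:
    """Max-min Euclidean distance by explicit double loops."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def directed(x, y):
        worst = 0.0
        for px in x:
            best = min(float(np.hypot(px[0] - py[0], px[1] - py[1])) for py in y)
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


def relabel_double_loop(p, image, m1, m2, uncontested, radius, alpha, beta):
    """Similarity-vote re-labeling by an explicit scan of the full disc."""
    img = np.asarray(image, dtype=float)
    la, lb = int(m1[p]), int(m2[p])
    sum_a = sum_b = 0.0
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            if (y, x) == tuple(p) or not uncontested[y, x]:
                continue
            d2 = (y - p[0]) ** 2 + (x - p[1]) ** 2
            if d2 > radius * radius:
                continue
            sim = np.exp(
                -(d2 / (2 * alpha**2) + (img[y, x] - img[p]) ** 2 / (2 * beta**2))
            )
            if m1[y, x] == la:
                sum_a += sim
            if m1[y, x] == lb:
                sum_b += sim
    return la if sum_a > sum_b else lb
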