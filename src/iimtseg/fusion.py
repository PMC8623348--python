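"""Similarity-weighted fusion of two segmentation label maps.

Two label maps of the same image (e.g. one computed on the original image
and one on its smoothed base layer) are combined pixelwise.  Pixels on
which the maps agree ("uncontested") keep their label.  Each disagreeing
("controversial") pixel p is re-labeled by comparing, over the uncontested
pixels q within a Euclidean disc of radius r around p, the summed
similarities

    SIM(p, q) = exp(-( Dis(p,q)^2 / (2*alpha^2) + |I(p)-I(q)|^2 / (2*beta^2) ))

of the neighbors carrying p's first-map label l_a against those carrying
its second-map label l_b; p receives l_a iff the l_a sum is strictly
greater, otherwise l_b (ties and empty neighborhoods fall to l_b).
Intensities are on the 0-255 gray scale and distances in pixel units, so
with the defaults alpha = beta = 1 the vote is dominated by the nearest
equal-intensity uncontested neighbors.

Only uncontested neighbors vote: controversial neighbors have no defined
label at voting time, which keeps the result independent of visit order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FusionConfig",
    "IncompatibleMapsError",
    "similarity",
    "split_pixels",
    "relabel",
    "fuse",
]


class IncompatibleMapsError(ValueError):
    """Label maps have different shapes (or class counts)."""


@dataclass
class FusionConfig:
    """Fusion neighborhood and similarity-kernel parameters.

    radius : Euclidean disc radius in pixels (default 12).
    alpha : spatial bandwidth of the similarity kernel (default 1).
    beta : intensity bandwidth on the 0-255 gray scale (default 1).
    square_neighborhood : use the circumscribing square instead of the disc.
    """

    radius: float = 12.0
    alpha: float = 1.0
    beta: float = 1.0
    square_neighborhood: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("radius, alpha and beta must be positive")


def similarity(
    p: tuple[int, int],
    q: tuple[int, int],
    image: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> float:
    """Spatial-intensity similarity of two pixels; 1 at p = q, symmetric."""
    img = np.asarray(image, dtype=float)
    dis2 = float((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
    di2 = float(img[p] - img[q]) ** 2
    return float(np.exp(-(dis2 / (2.0 * alpha**2) + di2 / (2.0 * beta**2))))


def split_pixels(m1: np.ndarray, m2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition pixels into (uncontested, controversial) boolean masks."""
    a = np.asarray(m1)
    b = np.asarray(m2)
    if a.shape != b.shape:
        raise IncompatibleMapsError(f"shape mismatch: {a.shape} vs {b.shape}")
    uncontested = a == b
    return uncontested, ~uncontested


def _neighborhood(
    p: tuple[int, int], shape: tuple[int, int], config: FusionConfig
) -> tuple[slice, slice, np.ndarray]:
    """Window slices around p and the in-neighborhood mask within the window."""
    r = config.radius
    ri = int(np.floor(r))
    y, x = p
    y0, y1 = max(0, y - ri), min(shape[0], y + ri + 1)
    x0, x1 = max(0, x - ri), min(shape[1], x + ri + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist2 = (yy - y) ** 2 + (xx - x) ** 2
    if config.square_neighborhood:
        inside = np.ones_like(dist2, dtype=bool)
    else:
        inside = dist2 <= r * r
    inside[y - y0, x - x0] = False  # p itself never votes
    return slice(y0, y1), slice(x0, x1), inside


def relabel(
    p: tuple[int, int],
    image: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    uncontested: np.ndarray,
    config: FusionConfig | None = None,
) -> int:
    """Re-label one controversial pixel by similarity-weighted voting."""
    if config is None:
        config = FusionConfig()
    img = np.asarray(image, dtype=float)
    la = int(m1[p])
    lb = int(m2[p])
    ys, xs, inside = _neighborhood(p, img.shape, config)
    voters = inside & uncontested[ys, xs]
    if not voters.any():
        return lb
    labels = np.asarray(m1)[ys, xs][voters]  # == m2 labels on uncontested pixels
    yy, xx = np.mgrid[ys, xs]
    dist2 = ((yy - p[0]) ** 2 + (xx - p[1]) ** 2)[voters].astype(float)
    di2 = (img[ys, xs][voters] - img[p]) ** 2
    sims = np.exp(
        -(dist2 / (2.0 * config.alpha**2) + di2 / (2.0 * config.beta**2))
    )
    sum_a = sims[labels == la].sum()
    sum_b = sims[labels == lb].sum()
    return la if sum_a > sum_b else lb


def fuse(
    m1: np.ndarray,
    m2: np.ndarray,
    image: np.ndarray,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Fuse two label maps: keep agreements, re-vote disagreements.

    Every output label equals either the pixel's m1 label or its m2 label;
    ``fuse(m, m, image) == m``.
    """
    if config is None:
        config = FusionConfig()
    uncontested, controversial = split_pixels(m1, m2)
    out = np.asarray(m1).copy()
    for p in zip(*np.nonzero(controversial)):
        out[p] = relabel((int(p[0]), int(p[1])), image, m1, m2, uncontested, config)
    return out
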