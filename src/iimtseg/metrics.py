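"""Segmentation quality measures.

Four measures are provided:

* **Uniformity** ``U`` — unsupervised: penalizes within-class intensity
  variance of the segmented classes,

      U = 1 - 2*K * sum_j sum_{i in S_j} (I_i - Ave(S_j))^2
                    / (M*N * (Imax - Imin)^2),

  equal to 1 exactly when every class is internally constant.  The default
  normalizes by the squared dynamic range, which keeps U in [0, 1]
  (dimensionally consistent with the squared numerator); the first-power
  normalization is available via ``squared_range=False`` for compatibility
  with sources that print it that way.
* **Misclassification error** ``ME`` — supervised, binary: fraction of
  pixels whose foreground/background assignment disagrees with a reference
  map after binarizing both on a chosen foreground class.
* **Hausdorff distance** ``H`` — max over both directions of the farthest
  nearest-neighbor Euclidean distance between two pixel sets.
* **Jaccard index** ``J`` — intersection over union of two pixel sets.

ME, H and J are defined on binary regions; for a multilevel segmentation
the aggregate is the unweighted mean of the one-vs-rest value over classes
(background class optionally excluded).  This aggregation is a declared
convention of this package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "EmptyRegionError",
    "MetricsReport",
    "uniformity",
    "misclassification_error",
    "misclassification_error_multilevel",
    "hausdorff",
    "hausdorff_multilevel",
    "jaccard",
    "jaccard_multilevel",
    "evaluate",
]


class EmptyRegionError(ValueError):
    """Hausdorff distance is undefined for an empty pixel set."""


def uniformity(
    image: np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
    squared_range: bool = True,
) -> float:
    """Uniformity measure of a segmentation against the image it labels.

    ``k`` is the number of thresholds (classes minus one); by default it is
    inferred as ``labels.max()``.  A constant image yields U = 1.
    """
    img = np.asarray(image, dtype=float)
    lab = np.asarray(labels)
    if img.shape != lab.shape:
        raise ValueError("image and labels must have the same shape")
    if k is None:
        k = int(lab.max())
    k = max(int(k), 1)
    i_max, i_min = img.max(), img.min()
    if i_max == i_min:
        return 1.0
    sq_dev = 0.0
    for c in np.unique(lab):
        vals = img[lab == c]
        sq_dev += float(np.sum((vals - vals.mean()) ** 2))
    dyn = (i_max - i_min) ** 2 if squared_range else (i_max - i_min)
    return 1.0 - 2.0 * k * sq_dev / (img.size * dyn)


def misclassification_error(
    seg: np.ndarray, truth: np.ndarray, foreground_class: int
) -> float:
    """Binary misclassification error, one class against the rest.

    0 iff the binarized maps agree everywhere; 1 iff they are complements.
    Invariant to relabeling classes other than the foreground class.
    """
    s = np.asarray(seg)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValueError("seg and truth must have the same shape")
    sf = s == foreground_class
    tf = t == foreground_class
    correct = np.count_nonzero(sf & tf) + np.count_nonzero(~sf & ~tf)
    return 1.0 - correct / s.size


def misclassification_error_multilevel(
    seg: np.ndarray,
    truth: np.ndarray,
    n_classes: int | None = None,
    include_background: bool = True,
) -> float:
    """Unweighted mean of one-vs-rest ME over classes."""
    classes = _class_range(seg, truth, n_classes, include_background)
    return float(
        np.mean([misclassification_error(seg, truth, c) for c in classes])
    )


def _as_points(a) -> np.ndarray:
    pts = np.asarray(a, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of pixel coordinates")
    return pts


def hausdorff(a, b) -> float:
    """Hausdorff distance between two non-empty pixel-coordinate sets."""
    pa = _as_points(a)
    pb = _as_points(b)
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        raise EmptyRegionError("Hausdorff distance undefined for empty sets")
    # seed=0: the randomized scan order affects runtime only, not the value
    return max(
        directed_hausdorff(pa, pb, seed=0)[0], directed_hausdorff(pb, pa, seed=0)[0]
    )


def _region_points(labels: np.ndarray, c: int, boundary: bool) -> np.ndarray:
    mask = np.asarray(labels) == c
    if boundary and mask.any():
        mask = mask & ~binary_erosion(mask, border_value=0)
    return np.argwhere(mask).astype(float)


def hausdorff_multilevel(
    seg: np.ndarray,
    truth: np.ndarray,
    n_classes: int | None = None,
    include_background: bool = True,
    boundary: bool = False,
) -> float:
    """Mean per-class Hausdorff distance between region pixel sets.

    With ``boundary=True`` distances are computed between region boundary
    pixels instead of full regions.  Classes empty in either map are
    skipped with a warning.
    """
    classes = _class_range(seg, truth, n_classes, include_background)
    values = []
    for c in classes:
        pa = _region_points(seg, c, boundary)
        pb = _region_points(truth, c, boundary)
        if pa.shape[0] == 0 or pb.shape[0] == 0:
            warnings.warn(
                f"class {c} empty in one of the maps; skipped in Hausdorff aggregate",
                stacklevel=2,
            )
            continue
        values.append(hausdorff(pa, pb))
    if not values:
        raise EmptyRegionError("no class present in both maps")
    return float(np.mean(values))


def jaccard(a, b) -> float:
    """Jaccard index |A n B| / |A u B| of two pixel-coordinate sets.

    Two empty sets are identical regions: J = 1.
    """
    sa = {tuple(p) for p in np.asarray(a).reshape(-1, 2).tolist()}
    sb = {tuple(p) for p in np.asarray(b).reshape(-1, 2).tolist()}
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def jaccard_multilevel(
    seg: np.ndarray,
    truth: np.ndarray,
    n_classes: int | None = None,
    include_background: bool = True,
) -> float:
    """Unweighted mean of per-class Jaccard indices (mask-based)."""
    s = np.asarray(seg)
    t = np.asarray(truth)
    classes = _class_range(s, t, n_classes, include_background)
    values = []
    for c in classes:
        sm = s == c
        tm = t == c
        union = np.count_nonzero(sm | tm)
        values.append(1.0 if union == 0 else np.count_nonzero(sm & tm) / union)
    return float(np.mean(values))


def _class_range(seg, truth, n_classes, include_background) -> range:
    if n_classes is None:
        n_classes = int(max(np.max(seg), np.max(truth))) + 1
    start = 0 if include_background else 1
    if n_classes <= start:
        raise ValueError("no classes to aggregate over")
    return range(start, n_classes)


@dataclass
class MetricsReport:
    """Bundle of the four quality measures plus per-class breakdowns."""

    uniformity: float
    misclassification_error: float | None = None
    hausdorff: float | None = None
    jaccard: float | None = None
    per_class: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "U": self.uniformity,
            "ME": self.misclassification_error,
            "H": self.hausdorff,
            "J": self.jaccard,
            "per_class": self.per_class,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(
    image: np.ndarray,
    seg: np.ndarray,
    truth: np.ndarray | None = None,
    k: int | None = None,
    include_background: bool = True,
    boundary_hausdorff: bool = False,
) -> MetricsReport:
    """Compute all applicable measures for a segmentation.

    Uniformity is always computed (against ``image``); the supervised
    measures require a ground-truth label map.
    """
    if k is None:
        k = int(np.max(seg)) if truth is None else int(max(np.max(seg), np.max(truth)))
    report = MetricsReport(
        uniformity=uniformity(image, seg, k=k),
        config={
            "k": k,
            "include_background": include_background,
            "boundary_hausdorff": boundary_hausdorff,
        },
    )
    if truth is None:
        return report
    n_classes = k + 1
    classes = list(_class_range(seg, truth, n_classes, include_background))
    per_me = {c: misclassification_error(seg, truth, c) for c in classes}
    report.misclassification_error = float(np.mean(list(per_me.values())))
    report.jaccard = jaccard_multilevel(seg, truth, n_classes, include_background)
    per_j = {}
    for c in classes:
        sm = np.asarray(seg) == c
        tm = np.asarray(truth) == c
        union = np.count_nonzero(sm | tm)
        per_j[c] = 1.0 if union == 0 else np.count_nonzero(sm & tm) / union
    per_h = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in classes:
            pa = _region_points(seg, c, boundary_hausdorff)
            pb = _region_points(truth, c, boundary_hausdorff)
            if pa.shape[0] and pb.shape[0]:
                per_h[c] = hausdorff(pa, pb)
    report.hausdorff = float(np.mean(list(per_h.values()))) if per_h else None
    report.per_class = {"ME": per_me, "J": per_j, "H": per_h}
    return report
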