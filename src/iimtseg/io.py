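"""Image and label-map I/O.

Images are 8-bit grayscale PNG/TIFF (color inputs are converted by
luminance averaging); 2-D NIfTI slices are supported when nibabel is
installed.  Label maps are written as 8-bit indexed PNGs with a JSON
sidecar mapping each label to its gray-level interval, so results stay
lossless and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


class ImageIOError(IOError):
    pass


def read_gray_image(path: str | Path, nifti: bool = False) -> np.ndarray:
    """Read an 8-bit grayscale image from PNG/TIFF (or a 2-D NIfTI slice)."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"cannot read image: {path} does not exist")
    if nifti or path.suffix in (".nii", ".gz"):
        try:
            import nibabel as nib
        except ImportError as exc:  # pragma: no cover
            raise ImageIOError("NIfTI support requires nibabel") from exc
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ImageIOError(f"expected a 2-D NIfTI slice, got shape {data.shape}")
        lo, hi = data.min(), data.max()
        if hi > lo:
            data = (data - lo) / (hi - lo) * 255.0
        return np.rint(data).astype(np.uint8)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255)
    return arr.astype(np.uint8)


def write_gray_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_label_map(path: str | Path, labels: np.ndarray, thresholds=None) -> None:
    """Write labels as an 8-bit PNG plus a ``.json`` sidecar.

    The sidecar records the label → gray-interval correspondence when the
    generating thresholds are supplied.
    """
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max() > 255:
        raise ImageIOError("more than 256 labels cannot be stored as 8-bit")
    iio.imwrite(path, labels.astype(np.uint8))
    sidecar = {"n_classes": int(labels.max()) + 1}
    if thresholds is not None:
        t = [int(x) for x in np.asarray(thresholds).ravel()]
        edges = [-1] + t + [255]
        sidecar["thresholds"] = t
        sidecar["label_to_gray_interval"] = {
            str(i): [edges[i] + 1, edges[i + 1]] for i in range(len(edges) - 1)
        }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_label_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"cannot read label map: {path} does not exist")
    return iio.imread(path).astype(np.int64)
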