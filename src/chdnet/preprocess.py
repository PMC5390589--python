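"""Image loading, resizing and overlapping-patch extraction.

This is the shared front end of both PCA filter learning and the
convolutional forward pass: images are reduced to a single intensity
channel, brought to a fixed working size (default 32x32), cut into all
overlapping s1 x s2 patches at stride 1, and each patch has its own mean
removed so the downstream eigenfilters see zero-mean patch statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize

# ITU-R 601 luma weights for collapsing color input to one channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DEFAULT_WORKING_SIZE = (32, 32)


@dataclass
class Image:
    """A single-channel image: a 2-D grid of real intensities in [0, 255]."""

    pixels: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image requires a 2-D grid, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("Image has zero size")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PatchMatrix:
    """Vectorized overlapping patches of one image, one patch per column.

    Columns enumerate valid top-left corners row-major; each patch is
    flattened row-major, so column j has length s1*s2 and there are
    p = (m - s1 + 1) * (n - s2 + 1) columns.
    """

    columns: np.ndarray
    s1: int
    s2: int
    mean_removed: bool = field(default=False)

    @property
    def p(self) -> int:
        return self.columns.shape[1]


def load_image(path: str | Path, to_gray: bool = True) -> Image:
    """Read a raster image (PNG/JPEG/TIFF) as a float intensity grid.

    Color inputs are reduced to one channel with the fixed luma weights
    (0.299, 0.587, 0.114); grayscale inputs pass through unchanged.
    """
    path = Path(path)
    try:
        with PILImage.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError("multichannel input requires to_gray=True")
        arr = arr[..., :3] @ np.asarray(LUMA_WEIGHTS)
    return Image(arr, source=str(path))


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (m, n, 3+) array with the fixed luma weights."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    return arr[..., :3] @ np.asarray(LUMA_WEIGHTS)


def resize_image(img: Image, height: int, width: int) -> Image:
    """Bilinear resize to (height, width); a same-size request is the identity.

    Sampling uses the pixel-center (midpoint) convention: output pixel
    centers are mapped into the input grid and interpolated bilinearly,
    so constant images stay constant for any target size.
    """
    if height < 1 or width < 1:
        raise ValueError(f"target dims must be >= 1, got {(height, width)}")
    if img.shape == (height, width):
        return img
    out = _sk_resize(
        img.pixels,
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return Image(out, source=img.source)


def extract_patches(img: Image, s1: int, s2: int) -> PatchMatrix:
    """All overlapping s1 x s2 patches at stride 1, as a (s1*s2, p) matrix.

    Raises if the patch exceeds the image (valid positions only here; the
    convolution path applies zero padding separately).
    """
    m, n = img.shape
    if s1 > m or s2 > n:
        raise ValueError(f"patch {s1}x{s2} larger than image {m}x{n}")
    if s1 < 1 or s2 < 1:
        raise ValueError("patch dims must be >= 1")
    windows = np.lib.stride_tricks.sliding_window_view(img.pixels, (s1, s2))
    # (m-s1+1, n-s2+1, s1, s2) -> row-major corners as columns, row-major flatten
    cols = windows.reshape(-1, s1 * s2).T.copy()
    return PatchMatrix(cols, s1=s1, s2=s2)


def remove_patch_means(pm: PatchMatrix) -> PatchMatrix:
    """Subtract each column's own mean; idempotent, columns sum to zero."""
    cols = pm.columns - pm.columns.mean(axis=0, keepdims=True)
    return PatchMatrix(cols, s1=pm.s1, s2=pm.s2, mean_removed=True)
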