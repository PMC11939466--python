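"""Color-space conversion and geometric augmentation of image patches.

Images are numpy arrays of shape ``(H, W, 3)`` (channel-last), dtype float,
with RGB values in the unit interval.  8-bit files are divided by 255 on
load.  The YCbCr transform is the affine map

    [Y Cb Cr]^T = [16 128 128]^T + (1/256) * A @ [R G B]^T

with the fixed 3x3 matrix ``YCBCR_MATRIX`` below, applied to unit-scale RGB
by default (``rgb_scale="unit"``); ``rgb_scale="8bit"`` multiplies the input
by 255 first, the scale the matrix is conventionally used at.
"""

from __future__ import annotations

import enum
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile


YCBCR_OFFSET = np.array([16.0, 128.0, 128.0])
YCBCR_MATRIX = np.array(
    [
        [65.738, 129.057, 25.064],
        [-37.945, -74.494, 112.439],
        [112.439, -94.154, -18.285],
    ]
)


class AugmentationKind(enum.Enum):
    """The three label-preserving geometric transforms used for augmentation."""

    HORIZONTAL_FLIP = "horizontal_flip"
    VERTICAL_FLIP = "vertical_flip"
    ROTATE_180 = "rotate_180"


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) image, got shape {image.shape}"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have height and width >= 1")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError(
            "RGB values must lie in [0, 1]; divide 8-bit inputs by 255"
        )
    return image


def rgb_to_ycbcr(image: np.ndarray, rgb_scale: str = "unit") -> np.ndarray:
    """Convert an RGB image in [0, 1] to YCbCr.

    Parameters
    ----------
    image : (H, W, 3) array with values in [0, 1].
    rgb_scale : "unit" applies the matrix to the [0, 1] values directly;
        "8bit" rescales to [0, 255] first.

    Returns
    -------
    (H, W, 3) float array of Y, Cb, Cr values.
    """
    image = _validate_rgb(image)
    if rgb_scale == "8bit":
        image = image * 255.0
    elif rgb_scale != "unit":
        raise ValueError(f"unknown rgb_scale {rgb_scale!r}")
    return YCBCR_OFFSET + image @ YCBCR_MATRIX.T / 256.0


def apply_augmentation(image: np.ndarray, kind: AugmentationKind) -> np.ndarray:
    """Apply one of the three flips/rotations; works on RGB or YCbCr arrays.

    The horizontal flip reverses the x (column) index, the vertical flip the
    y (row) index; the 180-degree rotation reverses both and equals the two
    flips composed.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    kind = AugmentationKind(kind)
    if kind is AugmentationKind.HORIZONTAL_FLIP:
        return image[:, ::-1].copy()
    if kind is AugmentationKind.VERTICAL_FLIP:
        return image[::-1, :].copy()
    return image[::-1, ::-1].copy()


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF into a float (H, W, 3) array scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] RGB array as an 8-bit PNG (lossless round trip)."""
    image = _validate_rgb(image)
    data = np.round(image * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG as a boolean (H, W) array."""
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return arr > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask, dtype=bool)
    Image.fromarray((mask * np.uint8(255)), mode="L").save(Path(path))
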