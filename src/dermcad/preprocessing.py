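"""Noise reduction and hair-artifact removal for lesion photographs.

The stage mirrors standard dermoscopy preprocessing: convert to grayscale,
resize to a common 150x150 grid, median-filter to suppress impulsive
salt-pepper noise, and remove thin dark hair strokes with a bottom-hat
transform (morphological closing minus the image, which lights up exactly the
thin dark structures a disk-shaped structuring element cannot fit into)
followed by local-median inpainting of the detected hair pixels.

All border handling is edge replication.  Grayscale conversion uses the
ITU-R BT.601 luminance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

DEFAULT_SIDE = 150
DEFAULT_MEDIAN_WINDOW = 5
DEFAULT_SE_RADIUS = 5
DEFAULT_HAIR_THRESHOLD = 30.0


@dataclass(frozen=True)
class StructuringElement:
    """Disk-shaped flat structuring element for morphological operators."""

    radius: int
    shape: str = "disk"

    def __post_init__(self) -> None:
        if self.shape != "disk":
            raise ValueError("only disk structuring elements are supported")
        if self.radius < 1:
            raise ValueError("structuring element radius must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        return disk(self.radius).astype(bool)


def _check_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("grayscale image must be 2-D with both sides >= 3")
    return image


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B, rounded to uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("RGB image must have shape (H, W, 3)")
    lum = (
        0.299 * image[..., 0].astype(float)
        + 0.587 * image[..., 1].astype(float)
        + 0.114 * image[..., 2].astype(float)
    )
    return np.round(lum).astype(np.uint8)


def resize_to_standard(image: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Bilinear resampling to ``side`` x ``side``; preserves dtype."""
    if side < 8:
        raise ValueError("target side must be >= 8")
    image = np.asarray(image)
    shape = (side, side) + image.shape[2:]
    if image.shape[:2] == (side, side):
        return image.copy()
    out = _sk_resize(
        image.astype(float),
        shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def median_filter(image: np.ndarray, window: int = DEFAULT_MEDIAN_WINDOW) -> np.ndarray:
    """Square-window median filter with edge replication."""
    image = _check_gray(image)
    if window < 3 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 3")
    return ndimage.median_filter(image, size=window, mode="nearest")


def bottom_hat(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological closing minus the image; non-negative, highlights thin
    dark structures narrower than the structuring element."""
    image = _check_gray(image)
    if 2 * se.radius >= min(image.shape):
        raise ValueError("structuring element larger than half the image")
    closed = ndimage.grey_closing(
        image.astype(float), footprint=se.footprint, mode="nearest"
    )
    return closed - image.astype(float)


def _inpaint_local_median(image: np.ndarray, hole_mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by the median of nearby unmasked pixels, growing
    the window (5, 7, 9, ...) until it contains at least one valid pixel."""
    out = image.astype(float).copy()
    h, w = image.shape
    rows, cols = np.nonzero(hole_mask)
    for r, c in zip(rows, cols):
        half = 2
        while True:
            r0, r1 = max(r - half, 0), min(r + half + 1, h)
            c0, c1 = max(c - half, 0), min(c + half + 1, w)
            patch = image[r0:r1, c0:c1]
            valid = ~hole_mask[r0:r1, c0:c1]
            if valid.any():
                out[r, c] = np.median(patch[valid])
                break
            half += 1
            if half > max(h, w):  # pragma: no cover - guarded by caller
                break
    return out


def hair_mask(
    image: np.ndarray,
    se: StructuringElement,
    hair_threshold: float = DEFAULT_HAIR_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of hair pixels: thresholded bottom-hat response, dilated
    by one pixel to cover anti-aliased stroke fringes."""
    response = bottom_hat(image, se)
    mask = response > hair_threshold
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def remove_hair(
    image: np.ndarray,
    se: StructuringElement | None = None,
    hair_threshold: float = DEFAULT_HAIR_THRESHOLD,
) -> np.ndarray:
    """Detect hair strokes via the bottom-hat transform and inpaint them with
    the local median of surrounding non-hair pixels.

    If the detected mask covers more than half the image the threshold is
    degenerate; a warning is logged and the image is returned unmodified.
    """
    image = _check_gray(image)
    if se is None:
        se = StructuringElement(DEFAULT_SE_RADIUS)
    mask = hair_mask(image, se, hair_threshold)
    if not mask.any():
        return image.copy()
    if mask.mean() > 0.5:
        log.warning(
            "hair mask covers %.0f%% of the image; threshold %.1f looks "
            "degenerate, returning the image unmodified",
            100 * mask.mean(),
            hair_threshold,
        )
        return image.copy()
    out = _inpaint_local_median(image, mask)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def preprocess_rgb(
    image: np.ndarray,
    side: int = DEFAULT_SIDE,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    se: StructuringElement | None = None,
    hair_threshold: float = DEFAULT_HAIR_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing of an RGB photograph.

    Resizes, median-filters each channel, detects hair on the grayscale
    bottom-hat response, and inpaints the hair pixels in every channel.
    Returns ``(rgb_clean, gray_clean)`` -- the cleaned color image for
    segmentation and its grayscale counterpart for descriptor extraction.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("RGB image must have shape (H, W, 3)")
    if se is None:
        se = StructuringElement(DEFAULT_SE_RADIUS)
    image = resize_to_standard(image, side)
    channels = [median_filter(image[..., c], median_window) for c in range(3)]
    gray = to_grayscale(np.stack(channels, axis=-1))
    mask = hair_mask(gray, se, hair_threshold)
    if mask.any() and mask.mean() <= 0.5:
        channels = [
            np.clip(np.round(_inpaint_local_median(ch, mask)), 0, 255).astype(np.uint8)
            for ch in channels
        ]
    rgb_clean = np.stack(channels, axis=-1)
    return rgb_clean, to_grayscale(rgb_clean)
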