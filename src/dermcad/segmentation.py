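"""Lesion segmentation: per-channel Otsu thresholds, mask fusion, and cleanup.

Pigmented lesions are darker than the surrounding skin, so each RGB plane is
thresholded with Otsu's criterion and the darker side taken as lesion.  The
three plane masks are fused (majority vote by default), then cleaned by
morphological opening, an iterative binary median smoother (7x7 -> 5x5 ->
3x3), an adaptive open-close filter iterated to a fixed point, and a size
filter that drops components smaller than 5% of the image area.  The final
boundary is traced as the closed 8-connected contour of the largest surviving
component.

The whole module is deterministic: no RNG anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dermcad.preprocessing import StructuringElement

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class NoLesionFoundError(ValueError):
    """Raised when every candidate component is filtered out."""


@dataclass(frozen=True)
class SegmentationConfig:
    fusion: str = "majority"  # majority | union | intersection
    opening_se: StructuringElement = field(default_factory=lambda: StructuringElement(3))
    open_close_se: StructuringElement = field(default_factory=lambda: StructuringElement(3))
    open_close_max_iter: int = 5
    min_fraction: float = 0.05


def otsu_threshold(channel: np.ndarray) -> int:
    """Threshold t maximizing between-class variance over the 256-bin
    histogram; classes are {v < t} and {v >= t}; ties break toward smaller t."""
    channel = np.asarray(channel)
    values = np.clip(np.round(channel), 0, 255).astype(np.uint8)
    if values.min() == values.max():
        raise ValueError("constant image has no separable classes")
    hist = np.bincount(values.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    omega = np.cumsum(p)  # omega[i] = P(v <= i)
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    w0 = omega[:-1]  # class {v < t} for t = 1..255
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    sigma_b[valid] = (mu_total * w0[valid] - mu[:-1][valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    return int(np.argmax(sigma_b)) + 1  # argmax returns the first (smallest) max


def channel_masks(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-plane lesion masks: pixels on the darker side of each Otsu cut."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("RGB image must have shape (H, W, 3)")
    masks = []
    for c in range(3):
        t = otsu_threshold(image[..., c])
        masks.append(image[..., c] < t)
    return tuple(masks)


def fuse_masks(
    masks: tuple[np.ndarray, np.ndarray, np.ndarray], fusion: str = "majority"
) -> np.ndarray:
    """Combine the three plane masks into one (default: per-pixel 2-of-3 vote)."""
    a, b, c = (np.asarray(m, dtype=bool) for m in masks)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("masks must share dimensions")
    if fusion == "majority":
        return (a.astype(int) + b.astype(int) + c.astype(int)) >= 2
    if fusion == "union":
        return a | b | c
    if fusion == "intersection":
        return a & b & c
    raise ValueError(f"unknown fusion rule: {fusion}")


def _binary_open(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # border_value=1 for erosion / 0 for dilation emulates edge replication:
    # an all-true mask stays all-true
    eroded = ndimage.binary_erosion(mask, structure=footprint, border_value=1)
    return ndimage.binary_dilation(eroded, structure=footprint, border_value=0)


def _binary_close(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    dilated = ndimage.binary_dilation(mask, structure=footprint, border_value=0)
    return ndimage.binary_erosion(dilated, structure=footprint, border_value=1)


def morphological_open(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion then dilation; removes blobs that cannot contain the SE."""
    return _binary_open(np.asarray(mask, dtype=bool), se.footprint)


def iterative_median_smooth(mask: np.ndarray) -> np.ndarray:
    """Three binary median (majority) filters with windows 7, 5, 3 in order."""
    out = np.asarray(mask, dtype=bool)
    for window in (7, 5, 3):
        out = ndimage.median_filter(out.astype(np.uint8), size=window, mode="nearest") > 0
    return out


def open_close_filter(
    mask: np.ndarray, se: StructuringElement, max_iter: int = 5
) -> np.ndarray:
    """Alternate opening and closing until a fixed point or ``max_iter``."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    out = np.asarray(mask, dtype=bool)
    fp = se.footprint
    for _ in range(max_iter):
        new = _binary_close(_binary_open(out, fp), fp)
        if np.array_equal(new, out):
            break
        out = new
    return out


def size_filter(mask: np.ndarray, min_fraction: float = 0.05) -> np.ndarray:
    """Drop 8-connected components with area < ``min_fraction`` of the image."""
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError("min_fraction must be in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        return mask.copy()
    cutoff = min_fraction * mask.size
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= cutoff) + 1
    return np.isin(labels, keep)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        raise NoLesionFoundError("no lesion found: mask is empty")
    areas = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(areas)) + 1)


# Moore neighborhood in counterclockwise order (image coordinates, row down):
# E, NE, N, NW, W, SW, S, SE
_MOORE = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def trace_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed 8-connected boundary of the largest component.

    Moore-neighbor tracing, starting from the topmost-then-leftmost lesion
    pixel and walking counterclockwise (with respect to Cartesian axes,
    x = column, y = up).  A single-pixel component yields a 1-point contour.
    """
    mask = np.asarray(mask, dtype=bool)
    comp = _largest_component(mask)
    rows, cols = np.nonzero(comp)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = comp.shape

    def is_set(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and comp[r, c]

    contour = [start]
    # enter from the west of the start pixel (its W neighbor is background
    # because start is leftmost in the top row of the component)
    prev_dir = _MOORE.index((0, -1))
    current = start
    first_move: tuple[int, int] | None = None
    for _ in range(8 * comp.sum() + 8):
        found = False
        # scan the Moore neighborhood counterclockwise, beginning just after
        # the direction we entered from
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            dr, dc = _MOORE[d]
            nr, nc = current[0] + dr, current[1] + dc
            if is_set(nr, nc):
                move = (nr, nc)
                if current == start:
                    if first_move is None:
                        first_move = move
                    elif move == first_move:
                        return contour  # closed the loop (Jacob's criterion)
                contour.append(move)
                # next scan starts from the backtrack direction
                prev_dir = (d + 4) % 8
                current = move
                found = True
                break
        if not found:  # isolated pixel
            return contour
        if current == start:
            contour.pop()  # avoid duplicating the start point
    return contour  # pragma: no cover - loop always terminates above


def segment_lesion(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Full segmentation chain: per-channel Otsu -> fusion -> opening ->
    iterative median smoothing -> open-close filter -> size filter ->
    contour tracing.  Returns the final mask (largest component) and its
    boundary."""
    if config is None:
        config = SegmentationConfig()
    masks = channel_masks(image)
    fused = fuse_masks(masks, config.fusion)
    opened = morphological_open(fused, config.opening_se)
    smoothed = iterative_median_smooth(opened)
    stable = open_close_filter(smoothed, config.open_close_se, config.open_close_max_iter)
    sized = size_filter(stable, config.min_fraction)
    if not sized.any():
        raise NoLesionFoundError("no lesion found after size filtering")
    final = _largest_component(sized)
    contour = trace_contour(final)
    return final, contour


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)
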