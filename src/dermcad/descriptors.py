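"""Texture and gradient descriptors for lesion images.

Four descriptors are implemented from their defining formulas rather than
wrapped from a library, because their exact conventions (sign function with
s(0) = 1, raster bit order, 24-neighbor code space, cell sizes) are the core
of the method:

* **LBP** -- per-pixel code ``sum_p s(g_p - g_c) 2^p`` over the P = 8
  neighbors of the 3x3 square ring (circular sampling optional), histogrammed
  into 2^8 = 256 bins.
* **N-LBP** -- the same code over the 24 neighbors of the 5x5 square ring,
  giving a 2^24 = 16,777,216 code space stored as a sparse histogram.
* **HOG** -- magnitude-weighted orientation histograms over 8x8-pixel cells,
  L2-normalized in 2x2-cell blocks with stride 1 (Dalal-Triggs layout).
* **CS-HOG** -- HOG with the cell size reduced to 2x2 pixels.

A variance-based top-k filter (`select_features`) stands in for feature
selection ahead of classification; it is fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# raster-order offsets of the 3x3 and 5x5 square rings (center excluded);
# bit p of the code corresponds to offsets[p]
_OFFSETS_8 = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]
_OFFSETS_24 = [
    (dr, dc)
    for dr in (-2, -1, 0, 1, 2)
    for dc in (-2, -1, 0, 1, 2)
    if (dr, dc) != (0, 0)
]

NLBP_DOMAIN_SIZE = 2**24


@dataclass(frozen=True)
class LBPParams:
    """Neighborhood definition for the LBP code: P neighbors at radius R."""

    P: int = 8
    R: int = 1
    neighborhood_kind: str = "square"

    def __post_init__(self) -> None:
        if self.P <= 1:
            raise ValueError("P must be > 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.neighborhood_kind not in ("square", "circular"):
            raise ValueError("neighborhood_kind must be 'square' or 'circular'")
        if self.neighborhood_kind == "square" and self.P not in (8, 24):
            raise ValueError("square neighborhoods support P = 8 or P = 24 only")


@dataclass(frozen=True)
class HOGParams:
    cell_size: int = 8
    n_bins: int = 9
    block_size: int = 2
    block_stride: int = 1
    signed_orientation: bool = False
    norm_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.cell_size < 1 or self.block_size < 1 or self.block_stride < 1:
            raise ValueError("cell/block sizes and stride must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class SparseHistogram:
    """Sparse code histogram: mapping code -> count over a huge code space."""

    counts: dict[int, int]
    domain_size: int

    def __post_init__(self) -> None:
        for code in self.counts:
            if not (0 <= code < self.domain_size):
                raise ValueError(f"code {code} outside [0, {self.domain_size})")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        codes = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        vals = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        order = np.argsort(codes)
        return codes[order], vals[order]


def sign_threshold(x: np.ndarray | float) -> np.ndarray | int:
    """The LBP sign function: s(x) = 1 for x >= 0, else 0."""
    return np.where(np.asarray(x, dtype=float) >= 0, 1, 0)


def lbp_code(center: float, neighbors: np.ndarray) -> int:
    """LBP code of one pixel: sum_p s(g_p - g_c) 2^p, bit p = neighbor p."""
    neighbors = np.asarray(neighbors, dtype=float)
    bits = sign_threshold(neighbors - float(center))
    return int(np.dot(bits, 1 << np.arange(len(neighbors), dtype=np.int64)))


def _square_ring_codes(image: np.ndarray, offsets: list[tuple[int, int]], r: int) -> np.ndarray:
    """Vectorized LBP codes at every interior pixel for a square-ring
    neighborhood of half-width ``r``; returns an (H-2r, W-2r) int64 array."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    center = img[r : h - r, r : w - r]
    codes = np.zeros_like(center, dtype=np.int64)
    for p, (dr, dc) in enumerate(offsets):
        nb = img[r + dr : h - r + dr, r + dc : w - r + dc]
        codes += ((nb - center) >= 0).astype(np.int64) << p
    return codes


def _circular_codes(image: np.ndarray, params: LBPParams) -> np.ndarray:
    """Circular sampling with bilinear interpolation at angles 2*pi*p/P."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = int(np.ceil(params.R))
    center = img[r : h - r, r : w - r]
    codes = np.zeros_like(center, dtype=np.int64)
    rows = np.arange(r, h - r)[:, None]
    cols = np.arange(r, w - r)[None, :]
    for p in range(params.P):
        angle = 2.0 * np.pi * p / params.P
        dr = -params.R * np.sin(angle)
        dc = params.R * np.cos(angle)
        rr = rows + dr
        cc = cols + dc
        # clamp so the bilinear cell stays inside the image when a sample
        # lands exactly on the last row/column
        r0 = np.clip(np.floor(rr).astype(int), 0, h - 2)
        c0 = np.clip(np.floor(cc).astype(int), 0, w - 2)
        fr = rr - r0
        fc = cc - c0
        nb = (
            img[r0, c0] * (1 - fr) * (1 - fc)
            + img[r0, c0 + 1] * (1 - fr) * fc
            + img[r0 + 1, c0] * fr * (1 - fc)
            + img[r0 + 1, c0 + 1] * fr * fc
        )
        codes += ((nb - center) >= 0).astype(np.int64) << p
    return codes


def lbp_codes(image: np.ndarray, params: LBPParams | None = None) -> np.ndarray:
    """Code image over all pixels whose neighborhood fits inside the frame."""
    if params is None:
        params = LBPParams()
    image = np.asarray(image)
    if params.neighborhood_kind == "square":
        r = 1 if params.P == 8 else 2
        offsets = _OFFSETS_8 if params.P == 8 else _OFFSETS_24
        if min(image.shape) <= 2 * r:
            raise ValueError("image too small for the requested neighborhood")
        return _square_ring_codes(image, offsets, r)
    if min(image.shape) <= 2 * int(np.ceil(params.R)):
        raise ValueError("image too small for the requested neighborhood")
    return _circular_codes(image, params)


def lbp_histogram(image: np.ndarray, params: LBPParams | None = None) -> np.ndarray:
    """Dense raw-count histogram of LBP codes, length 2^P (256 for P = 8)."""
    if params is None:
        params = LBPParams()
    if params.P > 16:
        raise ValueError("dense histograms limited to P <= 16; use nlbp_histogram")
    codes = lbp_codes(image, params)
    return np.bincount(codes.ravel(), minlength=2**params.P).astype(np.int64)


def nlbp_histogram(image: np.ndarray) -> SparseHistogram:
    """24-neighbor LBP (5x5 square ring, raster bit order) accumulated into a
    sparse histogram over the 2^24-code domain."""
    image = np.asarray(image)
    if min(image.shape) < 5:
        raise ValueError("image must be at least 5x5 for the 24-neighbor code")
    codes = _square_ring_codes(image, _OFFSETS_24, 2)
    uniq, cnt = np.unique(codes.ravel(), return_counts=True)
    return SparseHistogram(
        counts={int(u): int(c) for u, c in zip(uniq, cnt)},
        domain_size=NLBP_DOMAIN_SIZE,
    )


def gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences Gx = I(x+1,y) - I(x-1,y), Gy = I(x,y+1) - I(x,y-1)
    (x = column, y = row), with edge replication at the borders."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    padded = np.pad(image, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return gx, gy


def gradient_polar(
    gx: np.ndarray, gy: np.ndarray, signed: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude sqrt(Gx^2 + Gy^2) and orientation atan2(Gy, Gx) in degrees,
    folded to [0, 180) unless ``signed``; orientation at zero magnitude is 0."""
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError("gradient fields must share dimensions")
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx))
    theta = np.mod(theta, 360.0 if signed else 180.0)
    theta[mag == 0] = 0.0
    return mag, theta


def _cell_histograms(
    mag: np.ndarray, theta: np.ndarray, params: HOGParams, n_cells: tuple[int, int]
) -> np.ndarray:
    """Magnitude-weighted orientation histograms per cell with soft (linear)
    binning between the two nearest bin centers (centers at i*span/n_bins)."""
    span = 360.0 if params.signed_orientation else 180.0
    width = span / params.n_bins
    t = theta / width
    b0 = np.floor(t).astype(int)
    frac = t - b0
    b0 %= params.n_bins
    b1 = (b0 + 1) % params.n_bins
    cy, cx = n_cells
    cs = params.cell_size
    rows = (np.arange(mag.shape[0]) // cs)[:, None] * np.ones(mag.shape[1], dtype=int)
    cols = np.ones((mag.shape[0], 1), dtype=int) * (np.arange(mag.shape[1]) // cs)[None, :]
    hist = np.zeros((cy, cx, params.n_bins))
    np.add.at(hist, (rows, cols, b0), mag * (1.0 - frac))
    np.add.at(hist, (rows, cols, b1), mag * frac)
    return hist


def hog_descriptor(image: np.ndarray, params: HOGParams | None = None) -> np.ndarray:
    """Block-normalized HOG vector.

    The image is cropped (top-left anchored) to the largest multiple of the
    cell size, per-cell histograms are computed, and each block of
    ``block_size`` x ``block_size`` cells (stride ``block_stride`` cells) is
    concatenated and L2-normalized with ``norm_epsilon``.  Output length is
    ``n_blocks_y * n_blocks_x * block_size^2 * n_bins``.
    """
    if params is None:
        params = HOGParams()
    image = np.asarray(image, dtype=float)
    cs, bs = params.cell_size, params.block_size
    cy, cx = image.shape[0] // cs, image.shape[1] // cs
    if cy < bs or cx < bs:
        raise ValueError("image smaller than one block")
    cropped = image[: cy * cs, : cx * cs]
    gx, gy = gradients(cropped)
    mag, theta = gradient_polar(gx, gy, params.signed_orientation)
    cells = _cell_histograms(mag, theta, params, (cy, cx))

    stride = params.block_stride
    blocks = []
    for by in range(0, cy - bs + 1, stride):
        for bx in range(0, cx - bs + 1, stride):
            v = cells[by : by + bs, bx : bx + bs].ravel()
            blocks.append(v / np.sqrt(np.dot(v, v) + params.norm_epsilon**2))
    return np.concatenate(blocks)


def cs_hog_descriptor(image: np.ndarray) -> np.ndarray:
    """HOG with the cell size reduced to 2x2 pixels, other parameters default."""
    return hog_descriptor(image, HOGParams(cell_size=2))


def hog_length(side: int, params: HOGParams | None = None) -> int:
    """Descriptor length for a square image of the given side."""
    if params is None:
        params = HOGParams()
    n_cells = side // params.cell_size
    n_blocks = (n_cells - params.block_size) // params.block_stride + 1
    return n_blocks * n_blocks * params.block_size**2 * params.n_bins


def select_features(train_matrix, k: int) -> np.ndarray:
    """Variance-based top-k filter fitted on training rows only.

    Drops zero-variance columns, then keeps the ``k`` columns with the largest
    training variance; returns the selected column indices sorted ascending,
    to be applied identically to train and test rows.  Accepts dense arrays
    or scipy.sparse matrices.
    """
    if hasattr(train_matrix, "tocsr"):  # scipy.sparse
        m = train_matrix.tocsr().astype(float)
        mean = np.asarray(m.mean(axis=0)).ravel()
        mean_sq = np.asarray(m.multiply(m).mean(axis=0)).ravel()
        var = mean_sq - mean**2
    else:
        var = np.var(np.asarray(train_matrix, dtype=float), axis=0)
    nonzero = np.flatnonzero(var > 0)
    if k > len(nonzero):
        warnings.warn(
            f"requested k={k} but only {len(nonzero)} non-constant features "
            "survive; returning all of them",
            stacklevel=2,
        )
        return np.sort(nonzero)
    order = np.argsort(-var[nonzero], kind="stable")
    return np.sort(nonzero[order[:k]])
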