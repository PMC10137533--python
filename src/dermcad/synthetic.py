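"""Seeded generator of lesion-like test images with ground-truth masks.

The generator emulates the salient structure of close-up photographs of
pigmented skin lesions: a single, roughly elliptical lesion darker than the
surrounding skin, with a class-dependent border irregularity and intensity
texture (melanomas: ragged border, heterogeneous pigment; nevi: smooth border,
homogeneous pigment), overlaid with thin dark hair strokes and impulsive
salt-pepper noise -- the acquisition artifacts the preprocessing stage is
designed to remove.

Labels follow the diagnostic convention used throughout the package:
melanoma = +1 (positive class), nevus = -1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import line_aa

MELANOMA = 1
NEVUS = -1

# class-conditional defaults: melanomas get ragged borders and heterogeneous
# pigment texture, nevi stay smooth and homogeneous
BORDER_IRREGULARITY = {MELANOMA: 0.3, NEVUS: 0.05}
TEXTURE_SD_LESION = {MELANOMA: 30.0, NEVUS: 8.0}

# fixed RGB tints applied to the scalar intensity field (skin reads redder,
# lesions read browner); channel order R, G, B
_SKIN_TINT = np.array([1.0, 0.84, 0.76])
_LESION_TINT = np.array([1.0, 0.78, 0.62])


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic lesion image generator.

    ``border_irregularity`` and ``texture_sd_lesion`` default to ``None``,
    which means "use the class-conditional default" for the label being
    generated.  ``n_hairs`` and ``hair_width`` may be a fixed int or an
    inclusive ``(lo, hi)`` range sampled per image.
    """

    image_size: int = 150
    lesion_radius_range: tuple[float, float] = (0.15, 0.35)
    border_irregularity: float | None = None
    lesion_mean: float = 70.0
    skin_mean: float = 180.0
    texture_sd_lesion: float | None = None
    n_hairs: int | tuple[int, int] = (0, 8)
    hair_width: int | tuple[int, int] = (1, 3)
    hair_intensity: float = 30.0
    salt_pepper_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("lesion_radius_range must lie within (0, 0.5)")
        for name in ("lesion_mean", "skin_mean", "hair_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if not (0.0 <= self.salt_pepper_fraction <= 0.2):
            raise ValueError("salt_pepper_fraction must be in [0, 0.2]")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        irr = self.border_irregularity
        if irr is not None and not (0.0 <= irr < 1.0):
            raise ValueError("border_irregularity must be in [0, 1)")
        # the perturbed lesion must fit inside the frame
        irr_max = max(BORDER_IRREGULARITY.values()) if irr is None else irr
        if hi * (1.0 + irr_max) >= 0.5:
            raise ValueError(
                "lesion_radius_range and border_irregularity would push the "
                "lesion outside the frame"
            )


@dataclass(frozen=True)
class LabeledSample:
    """One synthetic image with its ground-truth lesion mask and class label."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = lesion (pre-corruption geometry)
    label: int  # +1 melanoma, -1 nevus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("mask and image dimensions differ")
        if self.label not in (MELANOMA, NEVUS):
            raise ValueError("label must be +1 (melanoma) or -1 (nevus)")


def _sample_range(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def _boundary_profile(rng: np.random.Generator, irregularity: float) -> np.ndarray:
    """Smooth periodic radial perturbation, one value per degree, in [-irr, irr]."""
    angles = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    prof = np.zeros(360)
    if irregularity > 0.0:
        for harmonic in (2, 3, 5, 7, 11):
            amp = rng.uniform(0.2, 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            prof += amp * np.sin(harmonic * angles + phase)
        peak = np.max(np.abs(prof))
        if peak > 0:
            prof *= irregularity / peak
    return prof


def _lesion_mask(rng: np.random.Generator, params: SyntheticParams, irr: float) -> np.ndarray:
    size = params.image_size
    lo, hi = params.lesion_radius_range
    a = rng.uniform(lo, hi) * size
    b = rng.uniform(lo, hi) * size
    phi = rng.uniform(0.0, np.pi)
    # jitter the center while keeping the perturbed boundary inside the frame
    margin = max(a, b) * (1.0 + irr) + 2.0
    slack = max(size / 2.0 - margin, 0.0)
    cy = size / 2.0 + rng.uniform(-slack, slack)
    cx = size / 2.0 + rng.uniform(-slack, slack)

    prof = _boundary_profile(rng, irr)
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # base radius of the rotated ellipse along each pixel's direction
    rel = theta - phi
    r_ellipse = (a * b) / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    deg = np.mod(np.degrees(theta), 360.0).astype(int) % 360
    radius = r_ellipse * (1.0 + prof[deg])
    return dist <= radius


def _draw_hairs(rng: np.random.Generator, alpha: np.ndarray, params: SyntheticParams) -> None:
    """Accumulate anti-aliased hair-stroke coverage into ``alpha`` (max-blend)."""
    size = alpha.shape[0]
    n = _sample_range(rng, params.n_hairs)
    for _ in range(n):
        width = _sample_range(rng, params.hair_width)
        p0 = rng.uniform(0, size - 1, size=2)
        p1 = rng.uniform(0, size - 1, size=2)
        mid = (p0 + p1) / 2.0 + rng.uniform(-size / 6.0, size / 6.0, size=2)
        # quadratic bezier sampled as a polyline gives a gently curved strand
        t = np.linspace(0.0, 1.0, 40)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p1
        # perpendicular sub-strokes build up the requested stroke width
        direction = p1 - p0
        norm = np.hypot(*direction)
        perp = (
            np.array([-direction[1], direction[0]]) / norm
            if norm > 0
            else np.array([0.0, 1.0])
        )
        offsets = np.arange(width) - (width - 1) / 2.0
        for off in offsets:
            shifted = pts + off * perp
            for (r0, c0), (r1, c1) in zip(shifted[:-1], shifted[1:]):
                rr, cc, val = line_aa(
                    int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
                )
                keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
                rr, cc, val = rr[keep], cc[keep], val[keep]
                np.maximum.at(alpha, (rr, cc), val)


def generate_lesion_image(params: SyntheticParams, label: int) -> LabeledSample:
    """Render one synthetic lesion sample for the given class label.

    The ground-truth mask covers exactly the pixels inside the (possibly
    perturbed) ellipse boundary, before hair strokes and salt-pepper noise
    are painted on.  Identical ``params`` + ``label`` reproduce an identical
    sample.
    """
    if label not in (MELANOMA, NEVUS):
        raise ValueError("label must be +1 (melanoma) or -1 (nevus)")
    rng = np.random.default_rng(params.seed)
    irr = (
        BORDER_IRREGULARITY[label]
        if params.border_irregularity is None
        else params.border_irregularity
    )
    sd_lesion = (
        TEXTURE_SD_LESION[label]
        if params.texture_sd_lesion is None
        else params.texture_sd_lesion
    )
    sd_skin = 0.25 * sd_lesion  # healthy skin is smoother than the lesion

    size = params.image_size
    mask = _lesion_mask(rng, params, irr)

    base = np.full((size, size), params.skin_mean, dtype=float)
    base[mask] = params.lesion_mean
    noise = rng.normal(0.0, 1.0, size=(size, size))
    base[mask] += sd_lesion * noise[mask]
    base[~mask] += sd_skin * noise[~mask]

    tint = np.where(mask[..., None], _LESION_TINT, _SKIN_TINT)
    rgb = base[..., None] * tint

    alpha = np.zeros((size, size))
    _draw_hairs(rng, alpha, params)
    hair_rgb = params.hair_intensity * _LESION_TINT
    rgb = rgb * (1.0 - alpha[..., None]) + hair_rgb * alpha[..., None]

    if params.salt_pepper_fraction > 0.0:
        n_corrupt = int(round(params.salt_pepper_fraction * size * size))
        flat = rng.choice(size * size, size=n_corrupt, replace=False)
        values = np.where(rng.random(n_corrupt) < 0.5, 0.0, 255.0)
        rgb.reshape(-1, 3)[flat] = values[:, None]

    image = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return LabeledSample(image=image, mask=mask, label=label, seed=params.seed)


def generate_dataset(
    n_melanoma: int,
    n_nevus: int,
    params: SyntheticParams | None = None,
    seed: int = 0,
) -> list[LabeledSample]:
    """Generate ``n_melanoma`` + ``n_nevus`` samples with per-sample seeds.

    Per-sample seeds are derived deterministically from ``(seed, index)`` via
    :class:`numpy.random.SeedSequence`, so a dataset is reproducible and each
    sample could be regenerated in isolation.
    """
    if n_melanoma < 0 or n_nevus < 0:
        raise ValueError("sample counts must be non-negative")
    if params is None:
        params = SyntheticParams()
    samples: list[LabeledSample] = []
    labels = [MELANOMA] * n_melanoma + [NEVUS] * n_nevus
    for idx, label in enumerate(labels):
        sub = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
        samples.append(generate_lesion_image(replace(params, seed=sub), label))
    return samples


def save_dataset(samples: list[LabeledSample], out_dir: str | Path) -> Path:
    """Write images (PNG), masks (1-bit PNG), and a CSV manifest.

    Manifest columns: ``filename, label, mask_filename``.  Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "mask_filename"])
        for i, s in enumerate(samples):
            name = f"sample_{i:04d}.png"
            mask_name = f"sample_{i:04d}_mask.png"
            Image.fromarray(s.image).save(out / name)
            Image.fromarray(s.mask).convert("1").save(out / mask_name)
            writer.writerow([name, s.label, mask_name])
    return manifest


def load_dataset(manifest: str | Path) -> list[LabeledSample]:
    """Read a manifest written by :func:`save_dataset` back into samples."""
    manifest = Path(manifest)
    root = manifest.parent
    samples: list[LabeledSample] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(root / row["filename"]).convert("RGB"))
            mask_name = row.get("mask_filename") or ""
            if mask_name:
                mask = np.asarray(Image.open(root / mask_name).convert("1"), dtype=bool)
            else:
                mask = np.zeros(image.shape[:2], dtype=bool)
            samples.append(
                LabeledSample(image=image, mask=mask, label=int(row["label"]))
            )
    return samples
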