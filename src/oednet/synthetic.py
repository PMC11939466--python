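"""Synthetic H&E-like slides with per-class ground-truth masks.

The generator emulates the *statistical structure* of the two architectural
dysplastic features, not their biology:

  * background ("others"): an eosin-pink field stippled with
    hematoxylin-purple nucleus dots arranged in ordered horizontal strata --
    regular rows at a fixed spacing, the analog of even epithelial
    stratification;
  * irregular-stratification regions: the same dots but with their
    positions jittered by ``stratification_disorder`` times the row spacing
    and their radii broadened, so the layered arrangement becomes uneven;
  * bulbous-rete-ridge regions: filled teardrop blobs (broad base, narrow
    top) in the nucleus hue.

Masks are binary, class-disjoint, and mark exactly the perturbed/blob
regions.  A seed fixes the output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .signatures import (RegionAnnotation, SignatureLibrary,
                         extract_signatures)

EOSIN_PINK = (0.91, 0.73, 0.83)
HEMATOXYLIN_PURPLE = (0.38, 0.22, 0.54)


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    image_size: int = 1050
    n_images: int = 20
    seed: int = 0
    background_hue: tuple[float, float, float] = EOSIN_PINK
    nucleus_hue: tuple[float, float, float] = HEMATOXYLIN_PURPLE
    n_ridges: tuple[int, int] = (1, 3)  # inclusive range per slide
    n_strat_regions: tuple[int, int] = (1, 2)
    stratification_disorder: float = 0.75
    noise_sd: float = 0.02
    patch_size: int = 350
    stride: Optional[int] = None  # defaults to patch_size // 2
    row_spacing: int = 14
    dot_spacing: int = 11
    dot_radius: int = 3
    positive_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.image_size < self.patch_size:
            raise ValueError("image_size must be >= patch_size")
        if not 0.0 <= self.stratification_disorder <= 1.0:
            raise ValueError("stratification_disorder must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def extraction_stride(self) -> int:
        return self.stride if self.stride is not None else self.patch_size // 2


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = yy * yy + xx * xx <= r * r
    return yy[inside], xx[inside]


def _paint_dots(canvas: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                radii: np.ndarray, color: np.ndarray,
                rng: np.random.Generator) -> None:
    size = canvas.shape[0]
    shades = color[None, :] * rng.uniform(0.85, 1.15, size=(len(ys), 1))
    for y, x, r, shade in zip(ys, xs, radii, shades):
        dy, dx = _disk_offsets(r)
        py, px = y + dy, x + dx
        ok = (py >= 0) & (py < size) & (px >= 0) & (px < size)
        canvas[py[ok], px[ok]] = np.clip(shade, 0, 1)


def _teardrop_mask(size: int, cy: int, cx: int, height: int,
                   base_halfwidth: int) -> np.ndarray:
    """Filled teardrop: broad base at the bottom (row cy), tapering to a
    narrow top ``height`` rows above it, centered on column cx."""
    mask = np.zeros((size, size), dtype=bool)
    for k in range(height):
        y = cy - k
        if not 0 <= y < size:
            continue
        t = k / height  # 0 at base, 1 at top
        half = max(1, int(round(base_halfwidth * (1.0 - t) ** 0.6)))
        x0, x1 = max(0, cx - half), min(size, cx + half + 1)
        mask[y, x0:x1] = True
    return mask


def generate_slide(config: SyntheticConfig, seed: Optional[int] = None
                   ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One synthetic slide and its two class masks.

    Returns ``(image, {"irregular_stratification": mask,
    "bulbous_rete_ridge": mask})``; masks are boolean, disjoint, and the
    bulbous mask has exactly as many 8-connected components as ridges
    placed.

    Regions are placed in distinct patch-aligned grid cells with a small
    inset, which guarantees class-disjoint masks, one component per ridge,
    and that some extraction window (stride dividing the patch size) covers
    each region by more than half its area.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    size = config.image_size
    patch = config.patch_size
    strat_mask = np.zeros((size, size), dtype=bool)
    ridge_mask = np.zeros((size, size), dtype=bool)

    n_strat = int(rng.integers(config.n_strat_regions[0],
                               config.n_strat_regions[1] + 1))
    if config.stratification_disorder == 0.0:
        # zero jitter leaves the strata exactly as the background: there is
        # no perturbed region to mark
        n_strat = 0
    n_ridges = int(rng.integers(config.n_ridges[0], config.n_ridges[1] + 1))
    grid = size // patch
    cells = [(i, j) for i in range(grid) for j in range(grid)]
    if n_strat + n_ridges > len(cells):
        raise ValueError(
            f"cannot fit {n_strat + n_ridges} regions on a slide with "
            f"{len(cells)} patch-sized cells; increase image_size or reduce "
            "region counts")
    order = rng.permutation(len(cells))
    chosen = [cells[k] for k in order[:n_strat + n_ridges]]
    margin = 2

    for (ci, cj) in chosen[:n_strat]:
        r0, c0 = ci * patch, cj * patch
        h = int(rng.uniform(0.92, 1.0) * (patch - 2 * margin))
        w = int(rng.uniform(0.92, 1.0) * (patch - 2 * margin))
        r = r0 + margin + int(rng.integers(0, patch - 2 * margin - h + 1))
        c = c0 + margin + int(rng.integers(0, patch - 2 * margin - w + 1))
        strat_mask[r:r + h, c:c + w] = True

    for (ci, cj) in chosen[n_strat:]:
        r0, c0 = ci * patch, cj * patch
        height = int(rng.uniform(0.96, 1.0) * (patch - 2 * margin))
        halfw = int(rng.uniform(0.96, 1.0) * (patch // 2 - margin - 1))
        cy = r0 + margin + height - 1
        cx = c0 + patch // 2
        ridge_mask |= _teardrop_mask(size, cy, cx, height, halfw)

    # --- paint the image
    image = np.empty((size, size, 3))
    bg = np.asarray(config.background_hue)
    image[...] = bg
    # eosin texture: soft horizontal banding of the background
    band = 0.02 * np.sin(2 * np.pi * np.arange(size) / (4 * config.row_spacing))
    image += band[:, None, None] * 0.5
    nucleus = np.asarray(config.nucleus_hue)

    # nucleus dot lattice over the whole slide
    ys_rows = np.arange(config.row_spacing // 2, size, config.row_spacing)
    xs_cols = np.arange(config.dot_spacing // 2, size, config.dot_spacing)
    gy, gx = np.meshgrid(ys_rows, xs_cols, indexing="ij")
    gy = gy.ravel().astype(float)
    gx = gx.ravel().astype(float)
    # small lattice jitter everywhere so the background is not a perfect grid
    gy += rng.uniform(-1.0, 1.0, size=gy.shape)
    gx += rng.uniform(-1.0, 1.0, size=gx.shape)
    radii = np.full(gy.shape, config.dot_radius, dtype=float)

    yi = np.clip(gy.astype(int), 0, size - 1)
    xi = np.clip(gx.astype(int), 0, size - 1)
    in_strat = strat_mask[yi, xi]
    # disorder: positional scatter plus radius variability, uneven arrangement
    amp = config.stratification_disorder * config.row_spacing
    gy[in_strat] += rng.uniform(-amp, amp, size=int(in_strat.sum()))
    gx[in_strat] += rng.uniform(-amp, amp, size=int(in_strat.sum()))
    d = config.stratification_disorder
    radii[in_strat] = rng.uniform(
        max(1.0, config.dot_radius - 2.0 * d),
        config.dot_radius + 2.0 * d + 1e-9,
        size=int(in_strat.sum()))

    yi = np.clip(np.round(gy).astype(int), 0, size - 1)
    xi = np.clip(np.round(gx).astype(int), 0, size - 1)
    in_ridge = ridge_mask[yi, xi]
    keep = ~in_ridge
    _paint_dots(image, yi[keep], xi[keep], np.round(radii[keep]).astype(int),
                nucleus, rng)

    # ridges: solid nucleus-hue blobs with mild internal shading
    ry, rx = np.nonzero(ridge_mask)
    shade = 1.0 + 0.12 * np.sin(ry / 9.0) * np.cos(rx / 9.0)
    image[ry, rx] = np.clip(nucleus[None, :] * shade[:, None], 0, 1)

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    masks = {"irregular_stratification": strat_mask,
             "bulbous_rete_ridge": ridge_mask}
    return image, masks


def generate_blind_set(config: SyntheticConfig, n_images: int,
                       seed_offset: int = 10_000
                       ) -> list[tuple[np.ndarray, dict[str, np.ndarray]]]:
    """Slides withheld from library construction, for sliding-window
    evaluation; seeds are offset so they never collide with library slides."""
    return [generate_slide(config, seed=config.seed + seed_offset + i)
            for i in range(n_images)]


def generate_library(config: SyntheticConfig) -> SignatureLibrary:
    """Generate ``n_images`` slides, extract signatures on a regular grid,
    and split 80/20 into train and test by slide."""
    if config.n_images < 2:
        raise ValueError("need at least 2 slides for a train/test split")
    slides = []
    for i in range(config.n_images):
        image, masks = generate_slide(config, seed=config.seed + i)
        image_id = f"slide_{i:03d}"
        annotations = [
            RegionAnnotation(image_id, cls, mask)
            for cls, mask in masks.items() if mask.any()
        ]
        slides.append((image_id, image, annotations))
    n_test = max(1, int(round(0.2 * config.n_images)))
    train_sigs, test_sigs = [], []
    for i, (image_id, image, annotations) in enumerate(slides):
        sigs = extract_signatures(
            image, annotations, image_id=image_id,
            patch_size=config.patch_size, stride=config.extraction_stride,
            positive_fraction=config.positive_fraction)
        (test_sigs if i < n_test else train_sigs).extend(sigs)
    library = SignatureLibrary(train_sigs, test_sigs)
    counts = library.class_counts
    if min(counts.values()) == 0:
        missing = [k for k, v in counts.items() if v == 0]
        raise ValueError(
            f"generated library has no training patches for {missing}; "
            "increase n_images/image_size or lower positive_fraction")
    return library
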