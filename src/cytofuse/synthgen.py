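"""Synthetic single-cell microscope image generator.

Emulates the layout and statistical character of single-leukocyte crop
datasets (one folder per cytomorphological class, heavy class imbalance)
without any download: each image is a stained elliptical cell body with an
interior nucleus on a uniform background, with class-dependent size,
eccentricity, stain hue, and intra-cell texture grain.  Classes are made
separable by construction (disjoint parameter intervals) so downstream
feature extractors and classifiers can be exercised and their learning
verified end-to-end.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import ImageRecord, LabeledImageSet

__all__ = ["ClassRecipe", "generate_cell_image", "generate_dataset", "default_recipes"]


def _check_interval(name: str, lo: float, hi: float) -> None:
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ValueError(f"{name}: invalid interval [{lo}, {hi}]")


@dataclasses.dataclass
class ClassRecipe:
    """Morphological/photometric parameter ranges for one synthetic class.

    ``stain_hue_range`` is in degrees on the HSV circle; ``texture_grain``
    sets the spatial frequency (cycles across the cell) of the multiplicative
    intensity modulation inside the cell body.
    """

    name: str
    n_images: int
    cell_radius_range: tuple[float, float]
    eccentricity_range: tuple[float, float] = (0.0, 0.5)
    nucleus_fraction_range: tuple[float, float] = (0.3, 0.5)
    stain_hue_range: tuple[float, float] = (270.0, 300.0)
    texture_grain: float = 4.0
    background_gray: int = 230
    image_size: int = 96

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        _check_interval("cell_radius_range", *self.cell_radius_range)
        _check_interval("eccentricity_range", *self.eccentricity_range)
        _check_interval("nucleus_fraction_range", *self.nucleus_fraction_range)
        _check_interval("stain_hue_range", *self.stain_hue_range)
        if not (0 <= self.eccentricity_range[0] and self.eccentricity_range[1] < 1):
            raise ValueError("eccentricity must lie in [0, 1)")
        if not (0 < self.nucleus_fraction_range[0] and self.nucleus_fraction_range[1] < 1):
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        if self.cell_radius_range[0] <= 2:
            raise ValueError("cell radius must exceed 2 px")
        if not (0 <= self.background_gray <= 255):
            raise ValueError("background_gray must lie in [0, 255]")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Scalar HSV (h in degrees) to RGB in [0, 1]."""
    h = (h % 360.0) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def generate_cell_image(recipe: ClassRecipe, rng: np.random.Generator) -> ImageRecord:
    """Render one cell image; deterministic given (recipe, generator state).

    The cell is a filled rotated ellipse fully inside the frame, with a
    darker concentric nucleus ellipse and multiplicative sinusoidal texture
    grain; the stain colour is drawn from the recipe's hue range.
    """
    size = recipe.image_size
    r = rng.uniform(*recipe.cell_radius_range)
    ecc = rng.uniform(*recipe.eccentricity_range)
    # semi-axes with equal area pi*r^2: a = r/(1-e^2)^(1/4), b = a*sqrt(1-e^2)
    a = r / (1.0 - ecc**2) ** 0.25
    b = a * np.sqrt(1.0 - ecc**2)
    if a >= size / 2 - 2:
        raise ValueError("cell radius too large for the frame")
    theta = rng.uniform(0, np.pi)
    # keep the whole ellipse inside the frame
    margin = a + 1
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)

    hue = rng.uniform(*recipe.stain_hue_range)
    sat = rng.uniform(0.55, 0.8)
    val = rng.uniform(0.55, 0.75)
    cell_rgb = _hsv_to_rgb(hue, sat, val)
    nuc_rgb = _hsv_to_rgb(hue, min(1.0, sat + 0.15), max(0.0, val - 0.25))
    nuc_frac = rng.uniform(*recipe.nucleus_fraction_range)
    phase = rng.uniform(0, 2 * np.pi, size=2)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    q = (u / a) ** 2 + (v / b) ** 2
    cell = q <= 1.0
    nucleus = q <= nuc_frac  # area fraction nuc_frac of the cell ellipse

    img = np.full((size, size, 3), recipe.background_gray / 255.0)
    img[cell] = cell_rgb
    img[nucleus] = nuc_rgb

    # multiplicative texture grain inside the cell body
    grain = 1.0 + 0.12 * np.sin(
        2 * np.pi * recipe.texture_grain * u / (2 * a) + phase[0]
    ) * np.sin(2 * np.pi * recipe.texture_grain * v / (2 * b) + phase[1])
    img[cell] *= grain[cell, None]

    px = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    return ImageRecord(pixels=px, label=recipe.name, source="synthetic")


def generate_dataset(
    recipes: Sequence[ClassRecipe],
    out_dir: str | Path | None = None,
    rng: np.random.Generator | int | None = 0,
) -> LabeledImageSet:
    """Generate a full class-per-folder dataset from a list of recipes.

    Per-image RNG streams are derived from the master seed, the class name
    and the image index, so the dataset is reproducible and any one image
    can be regenerated in isolation.
    """
    if not recipes:
        raise ValueError("need at least one recipe")
    names = [r.name for r in recipes]
    if len(set(names)) != len(names):
        raise ValueError("recipe names must be unique")
    if isinstance(rng, np.random.Generator):
        master = int(rng.integers(0, 2**31 - 1))
    else:
        master = int(rng if rng is not None else 0)

    records = []
    for recipe in recipes:
        if recipe.n_images == 0:
            warnings.warn(f"class {recipe.name!r} has 0 requested images")
        for i in range(recipe.n_images):
            ss = np.random.SeedSequence([master, _stable_hash(recipe.name), i])
            rec = generate_cell_image(recipe, np.random.default_rng(ss))
            rec.seed_tag = f"synth:{master}:{recipe.name}:{i}"
            rec.ident = f"{recipe.name}/{i:05d}.png"
            records.append(rec)
    data = LabeledImageSet(records)
    if out_dir is not None:
        out = Path(out_dir)
        for recipe in recipes:  # empty classes still get their folder
            (out / recipe.name).mkdir(parents=True, exist_ok=True)
        data.write_tree(out)
    return data


def _stable_hash(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode()) & 0x7FFFFFFF


def default_recipes(
    counts: Sequence[int] = (60, 150, 400, 1200), image_size: int = 96
) -> list[ClassRecipe]:
    """The default 4-class long-tailed fixture.

    Four classes with disjoint stain-hue intervals and graded size/shape/
    texture parameters, mirroring the long-tailed class inventory of real
    cytomorphology collections at desk scale.
    """
    if len(counts) != 4:
        raise ValueError("default fixture has exactly 4 classes")
    s = image_size / 96.0
    return [
        ClassRecipe(
            name="blast_like",
            n_images=counts[0],
            cell_radius_range=(30 * s, 36 * s),
            eccentricity_range=(0.0, 0.3),
            nucleus_fraction_range=(0.55, 0.7),
            stain_hue_range=(250.0, 270.0),
            texture_grain=2.0,
            image_size=image_size,
        ),
        ClassRecipe(
            name="lympho_like",
            n_images=counts[1],
            cell_radius_range=(16 * s, 22 * s),
            eccentricity_range=(0.0, 0.3),
            nucleus_fraction_range=(0.6, 0.75),
            stain_hue_range=(200.0, 220.0),
            texture_grain=3.0,
            image_size=image_size,
        ),
        ClassRecipe(
            name="mono_like",
            n_images=counts[2],
            cell_radius_range=(26 * s, 34 * s),
            eccentricity_range=(0.5, 0.75),
            nucleus_fraction_range=(0.35, 0.5),
            stain_hue_range=(300.0, 330.0),
            texture_grain=5.0,
            image_size=image_size,
        ),
        ClassRecipe(
            name="neutro_like",
            n_images=counts[3],
            cell_radius_range=(20 * s, 28 * s),
            eccentricity_range=(0.2, 0.5),
            nucleus_fraction_range=(0.25, 0.4),
            stain_hue_range=(150.0, 180.0),
            texture_grain=8.0,
            image_size=image_size,
        ),
    ]
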