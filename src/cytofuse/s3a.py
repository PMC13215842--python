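"""Synthetic Acquisition Artifact Augmentation (S3A) class balancing.

Six photometric transforms emulating microscope acquisition artifacts —
brightness scaling, contrast stretch about the image mean, additive
Gaussian noise, salt-and-pepper noise, Gaussian defocus blur, and random
pixel dropout — composed stochastically and used to oversample minority
classes (and truncate majority classes) to a common per-class target count.

Transform parameter laws:

=====================  =================================
brightness factor a    Uniform(0.85, 1.12)
contrast factor b      Uniform(0.85, 1.2), about image mean mu
Gaussian noise sigma   5 (intensity units)
salt/pepper prob rho   0.002 (each polarity)
blur kernel            3 x 3 (sigma 0.8)
dropout prob p_d       0.005
=====================  =================================

Every transform clips to [0, 255] and rounds back to 8-bit so chains stay
composable and file-writable.  All stochastic transforms accept an explicit
seed recorded in :class:`ArtifactParams`, which makes every augmented image
exactly replayable from its manifest entry.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import ImageRecord, LabeledImageSet

__all__ = [
    "ALPHA_RANGE",
    "BETA_RANGE",
    "SIGMA_NOISE",
    "RHO_SALT_PEPPER",
    "P_DROPOUT",
    "BLUR_KERNEL",
    "TRANSFORM_NAMES",
    "ArtifactParams",
    "BalancePlan",
    "brightness",
    "contrast",
    "gaussian_noise",
    "salt_pepper",
    "gaussian_blur",
    "pixel_dropout",
    "apply_artifact_chain",
    "replay_chain",
    "balance_dataset",
]

ALPHA_RANGE = (0.85, 1.12)
BETA_RANGE = (0.85, 1.2)
SIGMA_NOISE = 5.0
RHO_SALT_PEPPER = 0.002
P_DROPOUT = 0.005
BLUR_KERNEL = (3, 3)
# sigma from kernel size k via the common 0.8*((k-1)*0.5 - 1) + 0.8 rule
BLUR_SIGMA = 0.8 * ((BLUR_KERNEL[0] - 1) * 0.5 - 1) + 0.8

TRANSFORM_NAMES = ("B_F", "C_F", "G_n", "SP_F", "G_B", "D_F")


def _to8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def _out(rec: ImageRecord, px: np.ndarray, source: str | None = None) -> ImageRecord:
    return ImageRecord(
        pixels=px,
        label=rec.label,
        source=source or rec.source,
        seed_tag=rec.seed_tag,
        ident=rec.ident,
    )


def brightness(img: ImageRecord, alpha: float) -> ImageRecord:
    """Scale every channel by ``alpha`` (clipped, rounded)."""
    return _out(img, _to8(img.pixels.astype(np.float64) * alpha))


def contrast(img: ImageRecord, beta: float) -> ImageRecord:
    """Stretch intensities about the image mean: ``beta*(i - mu) + mu``."""
    x = img.pixels.astype(np.float64)
    mu = x.mean()
    return _out(img, _to8(beta * (x - mu) + mu))


def gaussian_noise(
    img: ImageRecord, sigma: float = SIGMA_NOISE, rng: np.random.Generator | None = None
) -> ImageRecord:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` per pixel."""
    rng = rng if rng is not None else np.random.default_rng()
    x = img.pixels.astype(np.float64)
    return _out(img, _to8(x + rng.normal(0.0, sigma, size=x.shape)))


def salt_pepper(
    img: ImageRecord, rho: float = RHO_SALT_PEPPER, rng: np.random.Generator | None = None
) -> ImageRecord:
    """Set each pixel to 0 w.p. ``rho``, to 255 w.p. ``rho``, else keep it.

    A pixel here is a spatial location: the corruption is applied across all
    channels at once, matching single-sensor salt/pepper artifacts.
    """
    rng = rng if rng is not None else np.random.default_rng()
    h, w, _ = img.pixels.shape
    u = rng.random((h, w))
    out = img.pixels.copy()
    out[u < rho] = 0
    out[(u >= rho) & (u < 2 * rho)] = 255
    return _out(img, out)


def gaussian_blur(img: ImageRecord) -> ImageRecord:
    """3 x 3 Gaussian defocus blur per channel, reflective border."""
    x = img.pixels.astype(np.float64)
    radius = BLUR_KERNEL[0] // 2
    out = np.empty_like(x)
    for c in range(3):
        out[:, :, c] = ndimage.gaussian_filter(
            x[:, :, c], sigma=BLUR_SIGMA, radius=radius, mode="reflect"
        )
    return _out(img, _to8(out))


def pixel_dropout(
    img: ImageRecord, p_d: float = P_DROPOUT, rng: np.random.Generator | None = None
) -> ImageRecord:
    """Zero each pixel independently with probability ``p_d``."""
    rng = rng if rng is not None else np.random.default_rng()
    h, w, _ = img.pixels.shape
    out = img.pixels.copy()
    out[rng.random((h, w)) < p_d] = 0
    return _out(img, out)


_STOCHASTIC = {"G_n", "SP_F", "D_F"}


@dataclasses.dataclass
class ArtifactParams:
    """Sampled parameters of one applied transform chain.

    ``chain`` holds ``(name, params)`` pairs in application order; params of
    stochastic transforms include the integer ``seed`` of their noise
    stream, so :func:`replay_chain` reproduces the chained output
    bit-exactly.
    """

    chain: list[tuple[str, dict[str, Any]]]

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("chain must be non-empty")
        for name, _ in self.chain:
            if name not in TRANSFORM_NAMES:
                raise ValueError(f"unknown transform {name!r}")

    def describe(self) -> str:
        parts = []
        for name, p in self.chain:
            kv = ",".join(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}" for k, v in p.items())
            parts.append(f"{name}({kv})")
        return "|".join(parts)


def _apply_one(img: ImageRecord, name: str, params: dict[str, Any]) -> ImageRecord:
    if name == "B_F":
        return brightness(img, params["alpha"])
    if name == "C_F":
        return contrast(img, params["beta"])
    if name == "G_n":
        return gaussian_noise(img, params["sigma"], np.random.default_rng(params["seed"]))
    if name == "SP_F":
        return salt_pepper(img, params["rho"], np.random.default_rng(params["seed"]))
    if name == "G_B":
        return gaussian_blur(img)
    if name == "D_F":
        return pixel_dropout(img, params["p_d"], np.random.default_rng(params["seed"]))
    raise ValueError(f"unknown transform {name!r}")


def apply_artifact_chain(
    img: ImageRecord, rng: np.random.Generator
) -> tuple[ImageRecord, ArtifactParams]:
    """Sample and apply a random chain of 1-3 distinct transforms.

    Parameters are sampled per transform instance from the laws above; the
    fully-parameterised chain is returned for manifests and exact replay.
    """
    k = int(rng.integers(1, 4))
    names = list(rng.choice(TRANSFORM_NAMES, size=k, replace=False))
    chain: list[tuple[str, dict[str, Any]]] = []
    out = img
    for name in names:
        params: dict[str, Any] = {}
        if name == "B_F":
            params["alpha"] = float(rng.uniform(*ALPHA_RANGE))
        elif name == "C_F":
            params["beta"] = float(rng.uniform(*BETA_RANGE))
        elif name == "G_n":
            params["sigma"] = SIGMA_NOISE
        elif name == "SP_F":
            params["rho"] = RHO_SALT_PEPPER
        elif name == "D_F":
            params["p_d"] = P_DROPOUT
        if name in _STOCHASTIC:
            params["seed"] = int(rng.integers(0, 2**31 - 1))
        out = _apply_one(out, name, params)
        chain.append((name, params))
    out = _out(img, out.pixels, source="augmented")
    return out, ArtifactParams(chain=chain)


def replay_chain(img: ImageRecord, params: ArtifactParams) -> ImageRecord:
    """Re-apply a recorded chain; bit-identical to the original application."""
    out = img
    for name, p in params.chain:
        out = _apply_one(out, name, p)
    return _out(img, out.pixels, source="augmented")


@dataclasses.dataclass
class BalancePlan:
    """Per-class bookkeeping of a balancing run."""

    target: int
    per_class_deficit: dict[str, int]
    per_class_retained: dict[str, int]
    augmentations: list[dict[str, Any]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for c, d in self.per_class_deficit.items():
            if d < 0:
                raise ValueError("deficits must be >= 0")
            if self.per_class_retained[c] + d != self.target:
                raise ValueError("retained + generated must equal target")


def balance_dataset(
    data: LabeledImageSet,
    target: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> tuple[LabeledImageSet, BalancePlan]:
    """Balance every class to exactly ``target`` images.

    Minority classes (N_c < target) keep all originals and receive
    ``target - N_c`` augmented images generated by random artifact chains
    applied to uniformly drawn originals of that class; majority classes
    keep exactly the first ``target`` originals in lexicographic identifier
    order.  Fully reproducible given the master seed: per-augmentation RNG
    streams are derived from (seed, class, augmentation index).
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    counts = data.class_counts()
    if not counts:
        raise ValueError("cannot balance an empty dataset")
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"class {c!r} has no images to augment from")
    if isinstance(rng, np.random.Generator):
        master = int(rng.integers(0, 2**31 - 1))
    else:
        master = int(rng if rng is not None else 0)

    import zlib

    records = []
    deficits: dict[str, int] = {}
    retained: dict[str, int] = {}
    aug_log: list[dict[str, Any]] = []
    for cls in sorted(counts):
        originals = sorted(data.by_class(cls), key=lambda r: r.ident)
        n_c = len(originals)
        if n_c >= target:
            kept = originals[:target]
            records.extend(kept)
            deficits[cls] = 0
            retained[cls] = target
            continue
        records.extend(originals)
        delta = target - n_c
        deficits[cls] = delta
        retained[cls] = n_c
        cls_key = zlib.crc32(cls.encode()) & 0x7FFFFFFF
        for j in range(delta):
            ss = np.random.SeedSequence([master, cls_key, j])
            stream = np.random.default_rng(ss)
            src = originals[int(stream.integers(0, n_c))]
            aug, params = apply_artifact_chain(src, stream)
            aug.seed_tag = f"s3a:{master}:{cls}:{j}"
            aug.ident = f"{cls}/aug_{j:05d}.png"
            records.append(aug)
            aug_log.append(
                {
                    "image_path": aug.ident,
                    "label": cls,
                    "source_image": src.ident,
                    "chain": params.describe(),
                }
            )
    plan = BalancePlan(
        target=target,
        per_class_deficit=deficits,
        per_class_retained=retained,
        augmentations=aug_log,
    )
    return LabeledImageSet(records), plan


def write_balance_manifest(plan: BalancePlan, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        plan.augmentations, columns=["image_path", "label", "source_image", "chain"]
    ).to_csv(path, index=False)
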