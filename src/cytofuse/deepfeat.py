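"""Deep-embedding extraction: backbone trunk + global average pooling.

The embedding contract is: resize the RGB image to the backbone's input
size, apply its canonical normalization, run the convolutional trunk
without any classification head, and global-average-pool the final feature
maps into a d-vector (per-channel spatial mean).

The built-in backbone is a *stub*: a small, seed-deterministic stack of
random convolution layers honoring the identical contract.  It needs no
pretrained weights or network access and produces embeddings that are
informative enough (random projections of local image statistics) for the
fusion and classification stages to be exercised and tested end-to-end.
Externally trained backbones can be plugged in by passing any callable
mapping a preprocessed image batch to feature maps.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from skimage.transform import resize

from .datatypes import FeatureMatrix, ImageRecord, LabeledImageSet

__all__ = ["BackboneSpec", "global_average_pool", "embed_image", "build_feature_matrix"]


def global_average_pool(feature_maps: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of an H x W x C activation tensor."""
    fm = np.asarray(feature_maps, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError("expected H x W x C feature maps")
    return fm.mean(axis=(0, 1))


def _conv_valid(x: np.ndarray, kernels: np.ndarray, stride: int = 2) -> np.ndarray:
    """Valid-mode strided convolution, x: HxWxCin, kernels: kxkxCinxCout."""
    k = kernels.shape[0]
    h, w, cin = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    # im2col via stride tricks
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(oh, ow, k, k, cin),
        strides=(s0 * stride, s1 * stride, s0, s1, s2),
        writeable=False,
    )
    cols = windows.reshape(oh * ow, k * k * cin)
    out = cols @ kernels.reshape(k * k * cin, -1)
    return np.maximum(out, 0.0).reshape(oh, ow, -1)


@dataclasses.dataclass
class BackboneSpec:
    """Specification of an embedding backbone.

    ``name='stub'`` builds the seeded random trunk; any other name requires
    a user-supplied ``trunk`` callable (image batch -> H x W x C maps) plus
    ``preprocess``, letting externally trained networks satisfy the same
    contract.
    """

    name: str = "stub"
    input_size: int = 64
    embed_dim: int = 32
    seed: int = 0
    trunk: Callable[[np.ndarray], np.ndarray] | None = None
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if self.name == "stub":
            self._kernels = self._stub_kernels()
        elif self.trunk is None:
            raise ValueError(
                f"backbone {self.name!r} requires a trunk callable; only the "
                "seeded stub backbone is built in"
            )

    def _stub_kernels(self) -> list[np.ndarray]:
        rng = np.random.default_rng(np.random.SeedSequence([918273, self.seed]))
        dims = [3, 8, 16, self.embed_dim]
        kernels = []
        for cin, cout in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (9 * cin))
            kernels.append(rng.normal(0.0, scale, size=(3, 3, cin, cout)))
        return kernels

    def _stub_preprocess(self, x: np.ndarray) -> np.ndarray:
        return x / 127.5 - 1.0  # [0,255] -> [-1,1]

    def forward_maps(self, img01: np.ndarray) -> np.ndarray:
        """Preprocessed image -> final convolutional feature maps."""
        if self.name == "stub":
            x = img01
            for kern in self._kernels:
                x = _conv_valid(x, kern, stride=2)
            return x
        return self.trunk(img01)  # type: ignore[misc]


def embed_image(img: ImageRecord, spec: BackboneSpec) -> np.ndarray:
    """Resize, normalize, run the trunk, global-average-pool: one d-vector."""
    px = img.pixels.astype(np.float64)
    if px.shape[:2] != (spec.input_size, spec.input_size):
        px = resize(
            px,
            (spec.input_size, spec.input_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    pre = spec.preprocess or (spec._stub_preprocess if spec.name == "stub" else None)
    x = pre(px) if pre is not None else px
    vec = global_average_pool(spec.forward_maps(x))
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite embedding")
    return vec


def build_feature_matrix(data: LabeledImageSet, spec: BackboneSpec) -> FeatureMatrix:
    """Embed every image; rows aligned one-to-one with the dataset order."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    failures = []
    rows = []
    for rec in data:
        try:
            rows.append(embed_image(rec, spec))
        except Exception as exc:  # pragma: no cover - exercised via error test
            failures.append(f"{rec.ident}: {exc}")
    if failures:
        raise RuntimeError("embedding failed for: " + "; ".join(failures))
    d = rows[0].shape[0]
    return FeatureMatrix(
        np.stack(rows),
        data.labels,
        [f"{spec.name}_{j}" for j in range(d)],
        provenance=spec.name,
        idents=[r.ident for r in data],
    )
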