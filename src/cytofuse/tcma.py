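"""TCMA-Net: a CNN + Vision-Transformer hybrid classifier on pseudo-images.

Feature vectors (handcrafted, deep, or fused) are standardized, reshaped
row-major into an m x m grid with m = ceil(sqrt(d)) (zero-padding the
tail), and bilinearly resized to a 32 x 32 x 1 pseudo-image.  Two parallel
branches process the pseudo-image:

* CNN branch — three blocks of [conv3x3 + ReLU, conv3x3 + ReLU, batch
  norm, 2x2 max pool, dropout] with 32, 64 and 128 filters, flattened and
  passed through a 256-unit dense layer with dropout;
* ViT branch — 4 x 4 grid of 8 x 8 patches, learnable linear patch
  embedding (projection dim 32) plus learnable positional embeddings, two
  pre-norm transformer encoder layers with 2-head self-attention and a
  ReLU feed-forward network (width 2x the projection dim), flattened and
  passed through a dense layer with dropout.

The branch representations are concatenated and passed through two dense
layers before the softmax head.  Training minimizes categorical
cross-entropy with Adam at learning rate 1e-4, batch size 64.  All
randomness (initialization, shuffling, dropout) derives from the single
config seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .datatypes import FeatureMatrix
from .select_fuse import encode_labels

__all__ = [
    "StandardizerState",
    "standardize",
    "PseudoImage",
    "to_pseudo_image",
    "pseudo_image_batch",
    "partition_patches",
    "reassemble_patches",
    "TCMAConfig",
    "TCMAModel",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# standardization

@dataclasses.dataclass
class StandardizerState:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, M: FeatureMatrix) -> FeatureMatrix:
        safe = np.where(self.std == 0, 1.0, self.std)
        vals = (M.values - self.mean) / safe
        vals[:, self.std == 0] = 0.0
        return FeatureMatrix(vals, M.labels, M.column_names, M.provenance, M.idents)


def standardize(
    M: FeatureMatrix, state: StandardizerState | None = None
) -> tuple[FeatureMatrix, StandardizerState]:
    """Per-column z-score with population std; constant columns map to 0.

    Fit on the training rows and pass the returned state to transform any
    held-out rows with the same statistics.
    """
    if M.n == 0:
        raise ValueError("empty matrix")
    if state is None:
        state = StandardizerState(M.values.mean(axis=0), M.values.std(axis=0))
    return state.transform(M), state


# ---------------------------------------------------------------------------
# pseudo-image spatialization

@dataclasses.dataclass
class PseudoImage:
    pixels: np.ndarray  # 32 x 32 x 1
    m: int
    pad_count: int
    source_dim: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (32, 32, 1):
            raise ValueError("pseudo-image must be 32 x 32 x 1")
        if not (0 <= self.pad_count <= self.m**2 - self.source_dim + self.pad_count):
            raise ValueError("invalid pad count")


def _bilinear_matrix(src: int, dst: int) -> np.ndarray:
    """Separable bilinear interpolation weights (dst x src), pixel-centred.

    Exact identity when src == dst, which makes the d = 1024 pseudo-image
    round-trip bit-exact.
    """
    if src == dst:
        return np.eye(src)
    pos = (np.arange(dst) + 0.5) * src / dst - 0.5
    pos = np.clip(pos, 0, src - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    w = pos - lo
    A = np.zeros((dst, src))
    A[np.arange(dst), lo] += 1 - w
    A[np.arange(dst), hi] += w
    return A


def to_pseudo_image(x: np.ndarray) -> PseudoImage:
    """Spatialize one d-vector into a 32 x 32 x 1 pseudo-image.

    Row-major fill of the ceil(sqrt(d)) square, zero-padded tail, bilinear
    resize to 32 x 32.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = x.size
    if d == 0:
        raise ValueError("empty feature vector")
    m = int(np.ceil(np.sqrt(d)))
    pad = m * m - d
    grid = np.concatenate([x, np.zeros(pad)]).reshape(m, m)
    A = _bilinear_matrix(m, 32)
    img = A @ grid @ A.T
    return PseudoImage(pixels=img[:, :, None], m=m, pad_count=pad, source_dim=d)


def pseudo_image_batch(values: np.ndarray) -> np.ndarray:
    """Vectorized spatialization of an N x d matrix to N x 32 x 32 x 1."""
    values = np.asarray(values, dtype=np.float64)
    n, d = values.shape
    m = int(np.ceil(np.sqrt(d)))
    grids = np.zeros((n, m * m))
    grids[:, :d] = values
    grids = grids.reshape(n, m, m)
    A = _bilinear_matrix(m, 32)
    out = np.einsum("im,nmk,jk->nij", A, grids, A)
    return out[..., None].astype(np.float32)


def partition_patches(p: PseudoImage | np.ndarray, grid: int = 4) -> np.ndarray:
    """Non-overlapping row-major patches; (grid^2, side^2) flattened vectors."""
    img = p.pixels if isinstance(p, PseudoImage) else np.asarray(p)
    img = img[:, :, 0] if img.ndim == 3 else img
    h, w = img.shape
    if h != w or h % grid:
        raise ValueError("patch grid must divide the (square) image side")
    s = h // grid
    patches = img.reshape(grid, s, grid, s).transpose(0, 2, 1, 3)
    return patches.reshape(grid * grid, s * s)


def reassemble_patches(patches: np.ndarray, grid: int = 4) -> np.ndarray:
    """Inverse of :func:`partition_patches` (exact)."""
    t, ss = patches.shape
    if t != grid * grid:
        raise ValueError("patch count must equal grid^2")
    s = int(np.sqrt(ss))
    img = patches.reshape(grid, grid, s, s).transpose(0, 2, 1, 3)
    return img.reshape(grid * s, grid * s)


# ---------------------------------------------------------------------------
# model

@dataclasses.dataclass
class TCMAConfig:
    """Classifier hyperparameters (defaults: the published configuration)."""

    n_classes: int = 2
    input_size: int = 32
    patch_grid: int = 4
    projection_dim: int = 32
    transformer_layers: int = 2
    attention_heads: int = 2
    cnn_filters: tuple[int, int, int] = (32, 64, 128)
    cnn_dense: int = 256
    vit_dense: int = 256
    fusion_dense: tuple[int, int] = (128, 64)
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-4
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_size % self.patch_grid:
            raise ValueError("patch grid must tile the input exactly")

    @property
    def patch_size(self) -> int:
        return self.input_size // self.patch_grid

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class _PositionalEmbedding(nn.Layer):
    def __init__(self, t: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"P": rng.normal(0, 0.02, size=(t, d)).astype(np.float32)}

    def forward(self, x, train=False):
        return x + self.params["P"]

    def backward(self, dy):
        self.grads = {"P": dy.sum(axis=0)}
        return dy


class _TransformerEncoderLayer(nn.Layer):
    """Pre-norm encoder layer: x + MHA(LN(x)), then + FFN(LN(.))."""

    def __init__(self, d: int, heads: int, ffn_mult: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm(d)
        self.mha = nn.MultiHeadSelfAttention(d, heads, rng)
        self.ln2 = nn.LayerNorm(d)
        self.ffn = nn.Sequential(
            nn.Dense(d, ffn_mult * d, rng), nn.ReLU(), nn.Dense(ffn_mult * d, d, rng)
        )

    def sublayers(self):
        return [self.ln1, self.mha, self.ln2, *self.ffn.walk()]

    def forward(self, x, train=False):
        a = x + self.mha.forward(self.ln1.forward(x, train), train)
        return a + self.ffn.forward(self.ln2.forward(a, train), train)

    def backward(self, dy):
        da = dy + self.ln2.backward(self.ffn.backward(dy))
        return da + self.ln1.backward(self.mha.backward(da))


class TCMAModel:
    """The assembled two-branch network; see the module docstring."""

    def __init__(self, config: TCMAConfig, class_map: dict[str, int] | None = None):
        if class_map is not None and len(class_map) != config.n_classes:
            raise ValueError("class_map size must equal n_classes")
        self.config = config
        self.class_map = class_map
        rng = np.random.default_rng(np.random.SeedSequence([46321, config.seed]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([46322, config.seed])
        )
        c = config
        drop = lambda: nn.Dropout(c.dropout, self._dropout_rng)  # noqa: E731

        blocks = []
        cin = 1
        for f in c.cnn_filters:
            blocks += [
                nn.Conv2DSame(cin, f, rng),
                nn.ReLU(),
                nn.Conv2DSame(f, f, rng),
                nn.ReLU(),
                nn.BatchNorm(f),
                nn.MaxPool2x2(),
                drop(),
            ]
            cin = f
        side = c.input_size // 2 ** len(c.cnn_filters)
        self.cnn = nn.Sequential(*blocks, nn.Flatten())
        self.cnn_head = nn.Sequential(
            nn.Dense(side * side * c.cnn_filters[-1], c.cnn_dense, rng),
            nn.ReLU(),
            drop(),
        )

        t = c.patch_grid**2
        self.patch_embed = nn.Dense(c.patch_size**2, c.projection_dim, rng)
        self.pos_embed = _PositionalEmbedding(t, c.projection_dim, rng)
        self.encoders = [
            _TransformerEncoderLayer(c.projection_dim, c.attention_heads, 2, rng)
            for _ in range(c.transformer_layers)
        ]
        self.vit_head = nn.Sequential(
            nn.Flatten(),
            nn.Dense(t * c.projection_dim, c.vit_dense, rng),
            nn.ReLU(),
            drop(),
        )

        d1, d2 = c.fusion_dense
        self.fusion = nn.Sequential(
            nn.Dense(c.cnn_dense + c.vit_dense, d1, rng),
            nn.ReLU(),
            drop(),
            nn.Dense(d1, d2, rng),
            nn.ReLU(),
        )
        # zero-initialized head: softmax starts uniform (loss ln C at step 0)
        self.head = nn.Dense(d2, c.n_classes, rng)
        self.head.params["W"][:] = 0.0

    # -- plumbing ----------------------------------------------------------
    def all_layers(self) -> list[nn.Layer]:
        layers = list(self.cnn.walk()) + list(self.cnn_head.walk())
        layers += [self.patch_embed, self.pos_embed]
        for enc in self.encoders:
            layers += enc.sublayers()
        layers += list(self.vit_head.walk()) + list(self.fusion.walk()) + [self.head]
        return layers

    def _patches(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        g, s = self.config.patch_grid, self.config.patch_size
        p = x[..., 0].reshape(n, g, s, g, s).transpose(0, 1, 3, 2, 4)
        return p.reshape(n, g * g, s * s)

    def _unpatch_grad(self, dp: np.ndarray) -> np.ndarray:
        n = dp.shape[0]
        g, s = self.config.patch_grid, self.config.patch_size
        d = dp.reshape(n, g, g, s, s).transpose(0, 1, 3, 2, 4)
        return d.reshape(n, g * s, g * s)[..., None]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pseudo-image batch (N, 32, 32, 1) -> logits (N, C)."""
        x = np.asarray(x, dtype=np.float32)
        h_cnn = self.cnn_head.forward(self.cnn.forward(x, train), train)
        z = self.pos_embed.forward(self.patch_embed.forward(self._patches(x), train), train)
        for enc in self.encoders:
            z = enc.forward(z, train)
        h_vit = self.vit_head.forward(z, train)
        self._split_at = h_cnn.shape[1]
        fused = np.concatenate([h_cnn, h_vit], axis=1)
        return self.head.forward(self.fusion.forward(fused, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.fusion.backward(self.head.backward(dlogits))
        d_cnn, d_vit = dfused[:, : self._split_at], dfused[:, self._split_at :]
        self.cnn.backward(self.cnn_head.backward(d_cnn))
        dz = self.vit_head.backward(d_vit)
        for enc in reversed(self.encoders):
            dz = enc.backward(dz)
        self.patch_embed.backward(self.pos_embed.backward(dz))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(nn.softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.vstack(out)


def build_model(config: TCMAConfig, class_map: dict[str, int] | None = None) -> TCMAModel:
    """Construct an initialized (untrained) TCMA-Net from a config."""
    return TCMAModel(config, class_map)


def _one_hot(y: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros((y.size, c), dtype=np.float32)
    out[np.arange(y.size), y] = 1.0
    return out


def train(
    model: TCMAModel,
    X_train: FeatureMatrix | np.ndarray,
    y_train: Sequence[str] | np.ndarray | None = None,
    config: TCMAConfig | None = None,
) -> dict[str, list[float]]:
    """Train with Adam / categorical cross-entropy; returns per-epoch history.

    ``X_train`` may be a standardized :class:`FeatureMatrix` (labels taken
    from it unless ``y_train`` is given) or a raw feature array.  Rows are
    spatialized to pseudo-images once, then shuffled per epoch with the
    config-seeded generator.
    """
    config = config or model.config
    if isinstance(X_train, FeatureMatrix):
        values = X_train.values
        labels = list(y_train) if y_train is not None else X_train.labels
    else:
        values = np.asarray(X_train)
        labels = list(y_train)  # type: ignore[arg-type]
    if model.class_map is None:
        _, model.class_map = encode_labels(labels)
    y = np.array([model.class_map[l] for l in labels])
    model._train_dim = values.shape[1]
    X = pseudo_image_batch(values)
    onehot = _one_hot(y, config.n_classes)

    opt = nn.Adam(model.all_layers(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([46323, config.seed]))
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    n = X.shape[0]
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, onehot[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at step {len(losses)}"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss * idx.size)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)
    return history


def predict(
    model: TCMAModel, X: FeatureMatrix | np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Class probabilities and argmax labels for standardized features."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    if model.class_map is None:
        raise ValueError("model has no class map; train it first")
    train_dim = getattr(model, "_train_dim", None)
    if train_dim is not None and values.shape[1] != train_dim:
        raise ValueError(
            f"feature dimension {values.shape[1]} != training dimension {train_dim}"
        )
    probs = model.predict_proba(pseudo_image_batch(values))
    inv = {i: c for c, i in model.class_map.items()}
    labels = [inv[int(i)] for i in probs.argmax(axis=1)]
    return probs, labels


# ---------------------------------------------------------------------------
# persistence

def save_model(
    model: TCMAModel,
    out_dir,
    scaler: StandardizerState | None = None,
) -> None:
    """Persist a trained model: weights as .npz plus a JSON sidecar.

    The sidecar carries the config, the class map, the training feature
    dimension, and (optionally) the standardizer statistics so held-out
    data can be transformed identically at evaluation time.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.all_layers()):
        for k, v in layer.params.items():
            arrays[f"layer{i}:{k}"] = v
        if isinstance(layer, nn.BatchNorm):
            arrays[f"layer{i}:running_mean"] = layer.running_mean
            arrays[f"layer{i}:running_var"] = layer.running_var
    if scaler is not None:
        arrays["scaler:mean"] = scaler.mean
        arrays["scaler:std"] = scaler.std
    np.savez(out / "model.npz", **arrays)
    meta = {
        "config": model.config.to_dict(),
        "class_map": model.class_map,
        "train_dim": getattr(model, "_train_dim", None),
        "has_scaler": scaler is not None,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir) -> tuple[TCMAModel, StandardizerState | None]:
    """Rebuild a model saved by :func:`save_model` (bit-identical weights)."""
    import json
    from pathlib import Path

    mdir = Path(model_dir)
    meta = json.loads((mdir / "model.json").read_text())
    cfg_dict = dict(meta["config"])
    for key in ("cnn_filters", "fusion_dense"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = TCMAConfig(**cfg_dict)
    model = TCMAModel(config, meta["class_map"])
    if meta.get("train_dim") is not None:
        model._train_dim = int(meta["train_dim"])
    with np.load(mdir / "model.npz") as arrays:
        for i, layer in enumerate(model.all_layers()):
            for k in layer.params:
                layer.params[k] = arrays[f"layer{i}:{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = arrays[f"layer{i}:running_mean"]
                layer.running_var = arrays[f"layer{i}:running_var"]
        scaler = None
        if meta.get("has_scaler"):
            scaler = StandardizerState(arrays["scaler:mean"], arrays["scaler:std"])
    return model, scaler
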