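"""MinMax scaling, chi-square relevance filtering, and feature fusion.

The hybrid descriptors are built by column-wise concatenation of the
handcrafted block with a deep-embedding block, MinMax scaling to [0, 1],
and chi-square filtering against the class labels.  For continuous
non-negative features the chi-square statistic uses the standard
class-conditional column-sum contingency construction: the observed
frequency of feature j in class r is the sum of the scaled column over the
samples of class r, and the expected frequency is the column total times
the class share; the statistic is referred to a chi-square law with C-1
degrees of freedom.  Selection is either every column with p < 0.05 or the
top-k columns by statistic.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .datatypes import FeatureMatrix, LabeledImageSet

__all__ = [
    "MinMaxScalerState",
    "minmax_scale",
    "encode_labels",
    "decode_labels",
    "SelectionResult",
    "chi2_scores",
    "chi2_filter",
    "FusedMatrix",
    "fuse",
    "hadnet_pipeline",
]


@dataclasses.dataclass
class MinMaxScalerState:
    """Per-column min/max fitted on the training split."""

    col_min: np.ndarray
    col_max: np.ndarray

    def transform(self, M: FeatureMatrix) -> FeatureMatrix:
        rng = self.col_max - self.col_min
        safe = np.where(rng == 0, 1.0, rng)
        vals = (M.values - self.col_min) / safe
        vals[:, rng == 0] = 0.0  # constant columns map to 0
        return FeatureMatrix(vals, M.labels, M.column_names, M.provenance, M.idents)


def minmax_scale(
    M: FeatureMatrix, state: MinMaxScalerState | None = None
) -> tuple[FeatureMatrix, MinMaxScalerState]:
    """Map each column affinely onto [0, 1]; constant columns map to 0.

    Pass a previously fitted ``state`` to reuse training-split statistics on
    a held-out split (values are then clipped to [0, 1] so downstream
    chi-square inputs stay non-negative).
    """
    if M.n == 0:
        raise ValueError("empty matrix")
    if state is None:
        state = MinMaxScalerState(M.values.min(axis=0), M.values.max(axis=0))
        return state.transform(M), state
    out = state.transform(M)
    out.values = np.clip(out.values, 0.0, 1.0)
    return out, state


def encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, dict[str, int]]:
    """Map class names to 0..C-1 in lexicographic order."""
    classes = sorted(set(labels))
    if not classes:
        raise ValueError("no labels")
    mapping = {c: i for i, c in enumerate(classes)}
    return np.array([mapping[l] for l in labels], dtype=np.int64), mapping


def decode_labels(encoded: Sequence[int], mapping: dict[str, int]) -> list[str]:
    inv = {i: c for c, i in mapping.items()}
    return [inv[int(e)] for e in encoded]


@dataclasses.dataclass
class SelectionResult:
    chi2_scores: np.ndarray
    p_values: np.ndarray
    selected: list[int]
    mode: str
    k: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("p_threshold", "top_k"):
            raise ValueError("mode must be 'p_threshold' or 'top_k'")
        if self.mode == "top_k" and len(self.selected) != self.k:
            raise ValueError("top_k selection must have exactly k columns")


def chi2_scores(
    M_scaled: np.ndarray, labels_encoded: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistic and p-value per column.

    O_jr = sum of column j over samples of class r; E_jr = column total
    times n_r / N; chi2_j = sum_r (O_jr - E_jr)^2 / E_jr with C-1 degrees
    of freedom.  Columns with zero total get statistic 0 and p-value 1.
    """
    X = np.asarray(M_scaled, dtype=np.float64)
    if X.min() < 0:
        raise ValueError("chi-square selection requires non-negative features")
    y = np.asarray(labels_encoded)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    onehot = (y[:, None] == classes[None, :]).astype(np.float64)  # N x C
    observed = onehot.T @ X  # C x d
    class_share = onehot.mean(axis=0)  # C
    expected = class_share[:, None] * X.sum(axis=0)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / np.where(expected == 0, 1, expected), 0.0)
    scores = terms.sum(axis=0)
    p = chi2_dist.sf(scores, df=classes.size - 1)
    zero_total = X.sum(axis=0) == 0
    scores[zero_total] = 0.0
    p[zero_total] = 1.0
    return scores, p


def chi2_filter(
    M_scaled: FeatureMatrix,
    labels_encoded: np.ndarray | None = None,
    p_threshold: float = 0.05,
    mode: str = "p_threshold",
    k: int | None = None,
) -> SelectionResult:
    """Select columns by chi-square relevance to the class labels.

    ``mode='p_threshold'`` keeps every column with p < ``p_threshold``;
    ``mode='top_k'`` keeps the ``k`` largest statistics (ties broken by
    column index).
    """
    if labels_encoded is None:
        labels_encoded, _ = encode_labels(M_scaled.labels)
    scores, p = chi2_scores(M_scaled.values, labels_encoded)
    if mode == "p_threshold":
        selected = [int(j) for j in np.nonzero(p < p_threshold)[0]]
    elif mode == "top_k":
        if k is None or k < 0 or k > scores.size:
            raise ValueError("top_k mode needs 0 <= k <= number of columns")
        order = np.argsort(-scores, kind="stable")  # stable: ties by column index
        selected = sorted(int(j) for j in order[:k])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SelectionResult(scores, p, selected, mode, k)


class FusedMatrix(FeatureMatrix):
    """Concatenation [handcrafted block || deep block] with origin slices."""

    def __init__(self, hcf: FeatureMatrix, deep: FeatureMatrix):
        if hcf.n != deep.n:
            raise ValueError(f"row mismatch: {hcf.n} vs {deep.n}")
        if any(a and b and a != b for a, b in zip(hcf.idents, deep.idents)):
            raise ValueError("sample identifiers do not align")
        if hcf.labels != deep.labels:
            raise ValueError("label vectors do not align")
        super().__init__(
            np.hstack([hcf.values, deep.values]),
            hcf.labels,
            hcf.column_names + deep.column_names,
            provenance=f"{hcf.provenance}+{deep.provenance}",
            idents=[a or b for a, b in zip(hcf.idents, deep.idents)],
        )
        self.origin_slices = {
            "hcf": slice(0, hcf.d),
            "deep": slice(hcf.d, hcf.d + deep.d),
        }


def fuse(hcf: FeatureMatrix, deep: FeatureMatrix) -> FusedMatrix:
    """Column-wise fusion of a handcrafted and a deep feature matrix."""
    return FusedMatrix(hcf, deep)


def hadnet_pipeline(
    data: LabeledImageSet,
    backbone=None,
    mode: str = "p_threshold",
    k: int | None = None,
    masked_features: bool = False,
) -> tuple[FeatureMatrix, SelectionResult]:
    """Full fused-descriptor construction on one dataset.

    HCF extraction -> deep embedding -> column fusion -> MinMax scaling ->
    chi-square selection; returns the selected-column matrix (labels
    retained) and the selection result.  For split-aware use (fit scaling /
    selection on the training rows only) see
    :func:`cytofuse.pipeline.run_experiment`.
    """
    from .deepfeat import BackboneSpec, build_feature_matrix
    from .hcf import extract_hcf_table

    if backbone is None:
        backbone = BackboneSpec()
    hcf_m = extract_hcf_table(data, masked=masked_features)
    deep_m = build_feature_matrix(data, backbone)
    fused = fuse(hcf_m, deep_m)
    scaled, _ = minmax_scale(fused)
    enc, _ = encode_labels(scaled.labels)
    sel = chi2_filter(scaled, enc, mode=mode, k=k)
    return scaled.select_columns(sel.selected), sel
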