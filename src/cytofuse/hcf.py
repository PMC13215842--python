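"""Handcrafted descriptor extraction for single-leukocyte crops.

The 19-dimensional handcrafted feature (HCF) vector concatenates four
groups computed on the segmented cell:

* shape (4): area, major/minor axis of the best-fit ellipse, solidity;
* color (6): std of R, mean/std of HSV hue, mean/std of HSV saturation,
  mean of CIE-Lab b* (signed scale, neutral ~= 0);
* texture (7): intensity std, skewness, kurtosis (Pearson, i.e. the raw
  fourth standardized moment), Shannon entropy of the 256-bin histogram,
  and GLCM contrast / correlation / homogeneity;
* fractal (2): box-counting fractal dimension and lacunarity of the mask.

Segmentation is Otsu thresholding on the luma image followed by largest
connected component.  Color/texture statistics default to the whole frame
(single-cell crops are cell-dominated); a masked mode restricts them to the
segmented cell.

The group composition itself comes out of a random-forest importance
screen over larger candidate pools (8 shape, 12 color, 13 texture, 2
fractal descriptors); :func:`rf_group_select` implements that screen as a
real, reusable procedure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from skimage import color as skcolor
from skimage import measure
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import threshold_otsu

from .datatypes import FeatureMatrix, ImageRecord, LabeledImageSet

__all__ = [
    "CellMask",
    "segment_leukocyte",
    "shape_features",
    "color_features",
    "texture_features",
    "fractal_features",
    "fuse_handcrafted",
    "extract_hcf",
    "extract_hcf_table",
    "candidate_feature_table",
    "rf_group_select",
    "HCF_COLUMNS",
    "GROUP_SIZES",
]

GROUP_SIZES = {"shape": 4, "color": 6, "texture": 7, "fractal": 2}

HCF_COLUMNS = [
    "shape_area",
    "shape_major_axis",
    "shape_minor_axis",
    "shape_solidity",
    "color_r_std",
    "color_hue_mean",
    "color_hue_std",
    "color_sat_mean",
    "color_sat_std",
    "color_lab_b_mean",
    "tex_std",
    "tex_skew",
    "tex_kurtosis",
    "tex_entropy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "fractal_dimension",
    "lacunarity",
]

# GLCM configuration: distance 1, four angles averaged, 64 gray levels
GLCM_DISTANCES = (1,)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_LEVELS = 64


def _luma(px: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma in [0, 255]."""
    x = px.astype(np.float64)
    return 0.299 * x[:, :, 0] + 0.587 * x[:, :, 1] + 0.114 * x[:, :, 2]


@dataclasses.dataclass
class CellMask:
    mask: np.ndarray
    area_px: int
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != self.area_px:
            raise ValueError("area_px must equal the mask pixel count")


def segment_leukocyte(img: ImageRecord) -> CellMask:
    """Otsu threshold + largest connected component, cell as foreground.

    Polarity is fixed by the frame corners: if the corner pixels are mostly
    foreground the threshold picked the background side and the mask is
    inverted.
    """
    gray = _luma(img.pixels)
    if np.ptp(gray) == 0:
        raise ValueError("no object found: constant image")
    t = threshold_otsu(gray)
    fg = gray > t
    corners = np.array([fg[0, 0], fg[0, -1], fg[-1, 0], fg[-1, -1]])
    if corners.sum() >= 3:
        fg = ~fg
    if not fg.any():
        raise ValueError("no object found")
    lab = measure.label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    biggest = int(counts.argmax())
    mask = lab == biggest
    rows, cols = np.nonzero(mask)
    return CellMask(
        mask=mask,
        area_px=int(mask.sum()),
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def _regionprops(mask: CellMask):
    props = measure.regionprops(mask.mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    return props[0]


def shape_features(mask: CellMask) -> np.ndarray:
    """[area, major axis length, minor axis length, solidity]."""
    if mask.area_px < 3:
        raise ValueError("mask too small for ellipse fit / convex hull")
    p = _regionprops(mask)
    return np.array(
        [float(mask.area_px), p.axis_major_length, p.axis_minor_length, p.solidity]
    )


def _color_planes(img: ImageRecord):
    rgb = img.pixels.astype(np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    lab = skcolor.rgb2lab(rgb)
    return rgb, hsv, lab


def color_features(img: ImageRecord, mask: CellMask | None = None) -> np.ndarray:
    """[R std, hue mean, hue std, sat mean, sat std, Lab-b* mean].

    R and the HSV channels are on [0, 1]; Lab b* is on the signed CIE scale
    (achromatic input gives ~0).  With ``mask`` the statistics are restricted
    to the cell pixels.
    """
    rgb, hsv, lab = _color_planes(img)
    sel = mask.mask if mask is not None else np.ones(rgb.shape[:2], dtype=bool)
    r = rgb[:, :, 0][sel]
    h = hsv[:, :, 0][sel]
    s = hsv[:, :, 1][sel]
    b = lab[:, :, 2][sel]
    return np.array([r.std(), h.mean(), h.std(), s.mean(), s.std(), b.mean()])


def _entropy_bits(gray_u8: np.ndarray) -> float:
    hist = np.bincount(gray_u8.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm(gray_u8: np.ndarray) -> np.ndarray:
    q = (gray_u8 // (256 // GLCM_LEVELS)).astype(np.uint8)
    return graycomatrix(
        q,
        distances=GLCM_DISTANCES,
        angles=GLCM_ANGLES,
        levels=GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )


def texture_features(img: ImageRecord, mask: CellMask | None = None) -> np.ndarray:
    """[std, skewness, kurtosis, entropy, GLCM contrast, corr, homogeneity].

    First-order statistics are over the (optionally masked) luma pixels;
    the GLCM is always computed on the full quantized frame since
    co-occurrence offsets are not well defined on ragged masked regions.
    Constant images return 0 for skewness/kurtosis/correlation by
    convention.
    """
    gray = _luma(img.pixels)
    gray_u8 = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    vals = gray[mask.mask] if mask is not None else gray.ravel()
    std = float(vals.std())
    if std == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
    ent = _entropy_bits(gray_u8 if mask is None else gray_u8[mask.mask])

    glcm = _glcm(gray_u8)
    contrast = float(graycoprops(glcm, "contrast").mean())
    homogeneity = float(graycoprops(glcm, "homogeneity").mean())
    if np.ptp(gray_u8) == 0:
        corr = 0.0  # undefined for a single gray level
    else:
        corr = float(graycoprops(glcm, "correlation").mean())
    return np.array([std, skew, kurt, ent, contrast, corr, homogeneity])


def box_counts(mask: np.ndarray, b: int) -> np.ndarray:
    """Per-box foreground pixel counts on a grid of ``b`` x ``b`` boxes.

    The mask is zero-padded on the bottom/right to a multiple of ``b``.
    """
    m = np.asarray(mask, dtype=np.int64)
    h, w = m.shape
    hp, wp = -(-h // b) * b, -(-w // b) * b
    padded = np.zeros((hp, wp), dtype=np.int64)
    padded[:h, :w] = m
    return padded.reshape(hp // b, b, wp // b, b).sum(axis=(1, 3))


def fractal_features(
    mask: CellMask,
    lacunarity_box: int = 8,
    single_scale_b: int | None = None,
) -> np.ndarray:
    """[fractal dimension, lacunarity] of the binary mask.

    The fractal dimension is the least-squares slope of log N_b versus
    log(1/b) over dyadic box sizes b in {2, 4, ..., min(H, W)/2}, where N_b
    is the number of boxes containing foreground.  ``single_scale_b``
    switches to the literal single-scale ratio -log N_b / log b at that box
    size.  Lacunarity is var/mean^2 of the per-box occupancy counts over the
    occupied boxes at ``lacunarity_box``.
    """
    m = mask.mask
    if mask.area_px == 0:
        raise ValueError("empty mask")
    if mask.area_px == 1:
        return np.array([0.0, 0.0])
    side = min(m.shape)
    sizes = []
    b = 2
    while b <= side // 2:
        sizes.append(b)
        b *= 2
    if single_scale_b is not None:
        nb = int((box_counts(m, single_scale_b) > 0).sum())
        fd = -np.log(nb) / np.log(single_scale_b)
    elif len(sizes) < 2:
        fd = 0.0
    else:
        logs_n = np.log([max(1, int((box_counts(m, b) > 0).sum())) for b in sizes])
        logs_inv_b = np.log(1.0 / np.array(sizes, dtype=np.float64))
        fd = float(np.polyfit(logs_inv_b, logs_n, 1)[0])
    counts = box_counts(m, lacunarity_box)
    occ = counts[counts > 0].astype(np.float64)
    lac = float(occ.var() / occ.mean() ** 2) if occ.size else 0.0
    return np.array([fd, lac])


def fuse_handcrafted(
    shape: np.ndarray, color: np.ndarray, texture: np.ndarray, fractal: np.ndarray
) -> np.ndarray:
    """Concatenate the four group vectors into the 19-dim HCF vector."""
    for vec, (name, k) in zip((shape, color, texture, fractal), GROUP_SIZES.items()):
        if np.asarray(vec).shape != (k,):
            raise ValueError(f"{name} group must have length {k}")
    return np.concatenate([shape, color, texture, fractal])


def extract_hcf(img: ImageRecord, masked: bool = False) -> np.ndarray:
    """Extract the full 19-dim handcrafted vector for one image."""
    mask = segment_leukocyte(img)
    region = mask if masked else None
    return fuse_handcrafted(
        shape_features(mask),
        color_features(img, region),
        texture_features(img, region),
        fractal_features(mask),
    )


def extract_hcf_table(data: LabeledImageSet, masked: bool = False) -> FeatureMatrix:
    """HCF matrix for a whole dataset (rows aligned with dataset order)."""
    rows = np.stack([extract_hcf(rec, masked=masked) for rec in data])
    return FeatureMatrix(
        rows,
        data.labels,
        HCF_COLUMNS,
        provenance="hcf",
        idents=[r.ident for r in data],
    )


# ---------------------------------------------------------------------------
# candidate pools + RF importance screen

CANDIDATE_COLUMNS = {
    "shape": [
        "shape_area",
        "shape_major_axis",
        "shape_minor_axis",
        "shape_solidity",
        "shape_perimeter",
        "shape_eccentricity",
        "shape_extent",
        "shape_orientation",
    ],
    "color": [
        "color_r_std",
        "color_hue_mean",
        "color_hue_std",
        "color_sat_mean",
        "color_sat_std",
        "color_lab_b_mean",
        "color_r_mean",
        "color_g_mean",
        "color_b_mean",
        "color_v_mean",
        "color_v_std",
        "color_lab_b_std",
    ],
    "texture": [
        "tex_std",
        "tex_skew",
        "tex_kurtosis",
        "tex_entropy",
        "glcm_contrast",
        "glcm_correlation",
        "glcm_homogeneity",
        "glcm_energy",
        "glcm_dissimilarity",
        "glcm_asm",
        "tex_mean",
        "tex_median",
        "tex_range",
    ],
    "fractal": ["fractal_dimension", "lacunarity"],
}


def _candidate_vector(img: ImageRecord) -> np.ndarray:
    """All 35 candidate descriptors (8 shape, 12 color, 13 texture, 2 fractal)."""
    mask = segment_leukocyte(img)
    p = _regionprops(mask)
    shape = np.array(
        [
            float(mask.area_px),
            p.axis_major_length,
            p.axis_minor_length,
            p.solidity,
            p.perimeter,
            p.eccentricity,
            p.extent,
            p.orientation,
        ]
    )
    rgb, hsv, lab = _color_planes(img)
    color = np.concatenate(
        [
            color_features(img),
            [
                rgb[:, :, 0].mean(),
                rgb[:, :, 1].mean(),
                rgb[:, :, 2].mean(),
                hsv[:, :, 2].mean(),
                hsv[:, :, 2].std(),
                lab[:, :, 2].std(),
            ],
        ]
    )
    gray = _luma(img.pixels)
    gray_u8 = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    glcm = _glcm(gray_u8)
    texture = np.concatenate(
        [
            texture_features(img),
            [
                float(graycoprops(glcm, "energy").mean()),
                float(graycoprops(glcm, "dissimilarity").mean()),
                float(graycoprops(glcm, "ASM").mean()),
                gray.mean(),
                float(np.median(gray)),
                float(np.ptp(gray)),
            ],
        ]
    )
    return np.concatenate([shape, color, texture, fractal_features(mask)])


def candidate_feature_table(data: LabeledImageSet) -> FeatureMatrix:
    cols = [c for group in CANDIDATE_COLUMNS.values() for c in group]
    rows = np.stack([_candidate_vector(rec) for rec in data])
    return FeatureMatrix(
        rows, data.labels, cols, provenance="hcf_candidates", idents=[r.ident for r in data]
    )


def rf_group_select(
    feature_table: FeatureMatrix,
    labels: Sequence[str] | None = None,
    group_sizes: dict[str, int] | None = None,
    groups: dict[str, list[str]] | None = None,
    n_estimators: int = 200,
    seed: int = 0,
) -> list[int]:
    """Top-k columns per descriptor group by random-forest importance.

    A single seeded forest is fit on all candidate columns; within each
    group the ``group_sizes[group]`` columns with the highest mean impurity
    decrease are kept (ties broken by column order), and the selected
    indices are returned in the group's canonical column order.
    """
    from sklearn.ensemble import RandomForestClassifier

    labels = list(labels) if labels is not None else feature_table.labels
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes for importance screening")
    group_sizes = group_sizes or GROUP_SIZES
    groups = groups or CANDIDATE_COLUMNS
    name_to_idx = {c: j for j, c in enumerate(feature_table.column_names)}

    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(feature_table.values, labels)
    importance = forest.feature_importances_

    selected: list[int] = []
    for group, cols in groups.items():
        k = group_sizes[group]
        if len(cols) < k:
            raise ValueError(f"group {group!r} has fewer candidates than k={k}")
        idx = np.array([name_to_idx[c] for c in cols])
        # stable sort on negated importance => ties broken by column order
        top = idx[np.argsort(-importance[idx], kind="stable")[:k]]
        selected.extend(sorted(top.tolist(), key=lambda j: cols.index(feature_table.column_names[j])))
    return selected
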