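"""Brute-force oracles: tiny, pure, dependency-light reference computations.

Each function recomputes a quantity by direct enumeration of its
definition, independently of the library code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

# displacement per angle (degrees), distance 1
GLCM_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def glcm_bruteforce(img: np.ndarray, angle_deg: int, levels: int, distance: int = 1):
    """Symmetric normalized co-occurrence matrix + (contrast, corr, homog).

    Enumerates every pixel pair at the given displacement with an explicit
    double loop; correlation of a single-level image is returned as nan.
    """
    img = np.asarray(img)
    dr, dc = GLCM_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    h, w = img.shape
    P = np.zeros((levels, levels), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[img[r, c], img[r2, c2]] += 1
                P[img[r2, c2], img[r, c]] += 1  # symmetric
    total = P.sum()
    if total == 0:
        return P, (0.0, np.nan, 1.0)
    P /= total
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    si = np.sqrt(float((P * (i - mu_i) ** 2).sum()))
    sj = np.sqrt(float((P * (j - mu_j) ** 2).sum()))
    if si * sj == 0:
        corr = np.nan
    else:
        corr = float((P * (i - mu_i) * (j - mu_j)).sum() / (si * sj))
    return P, (contrast, corr, homogeneity)


def boxcount_bruteforce(mask: np.ndarray, b: int) -> int:
    """Number of b x b tiles (zero-padded grid) containing >= 1 foreground."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    n = 0
    for r0 in range(0, h, b):
        for c0 in range(0, w, b):
            if mask[r0 : r0 + b, c0 : c0 + b].any():
                n += 1
    return n


def chi2_bruteforce(X: np.ndarray, y: np.ndarray):
    """Per-column chi-square from the class-conditional column-sum table.

    O_jr = sum of column j over class r, E_jr = column total * class share;
    dof = C - 1.  Literal loop over columns and classes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    n = len(y)
    scores, pvals = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        total = col.sum()
        stat = 0.0
        for r in classes:
            o = col[y == r].sum()
            e = total * float((y == r).sum()) / n
            if e > 0:
                stat += (o - e) ** 2 / e
        scores.append(stat)
        pvals.append(float(chi2_dist.sf(stat, df=len(classes) - 1)) if total > 0 else 1.0)
    return np.array(scores), np.array(pvals)


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ellipse_pixel_count(h: int, w: int, cy: float, cx: float, a: float, b: float) -> int:
    """Pixels whose centres fall inside the axis-aligned ellipse."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return int((((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0).sum())
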