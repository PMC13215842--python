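"""Core in-memory containers shared across the pipeline.

The pipeline moves between three representations: labelled image
collections (class-per-folder trees of single-cell RGB crops), per-sample
feature matrices, and evaluation reports.  Everything here is a thin,
validated wrapper over numpy arrays / pandas frames so that each stage can
state its contract precisely.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "LabeledImageSet",
    "FeatureMatrix",
    "load_image_tree",
]


@dataclasses.dataclass
class ImageRecord:
    """A single 8-bit RGB cell image with its class label and provenance.

    ``source`` distinguishes freshly synthesised images, photometric
    augmentations and images loaded from disk; ``seed_tag`` records the RNG
    lineage so any image can be regenerated, and ``ident`` is a stable
    per-dataset identifier (relative file path once written).
    """

    pixels: np.ndarray
    label: str
    source: str = "synthetic"
    seed_tag: str = ""
    ident: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixel array, got {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("images must be at least 16 x 16")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.source not in ("synthetic", "augmented", "file"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


class LabeledImageSet:
    """Ordered collection of :class:`ImageRecord` with a class inventory."""

    def __init__(self, records: Sequence[ImageRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ImageRecord:
        return self.records[i]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.labels))

    def by_class(self, label: str) -> list[ImageRecord]:
        return [r for r in self.records if r.label == label]

    def subset(self, indices: Sequence[int]) -> "LabeledImageSet":
        return LabeledImageSet([self.records[i] for i in indices])

    def write_tree(self, out_dir: str | Path, manifest: str = "manifest.csv") -> Path:
        """Write the class-per-folder PNG tree plus a manifest CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        counters: Counter[str] = Counter()
        for rec in self.records:
            cls_dir = out / rec.label
            cls_dir.mkdir(exist_ok=True)
            if rec.ident:
                rel = Path(rec.ident)
                path = out / rel
                path.parent.mkdir(parents=True, exist_ok=True)
            else:
                idx = counters[rec.label]
                counters[rec.label] += 1
                path = cls_dir / f"{idx:05d}.png"
                rec.ident = str(path.relative_to(out))
            iio.imwrite(path, rec.pixels, extension=".png")
            rows.append({"image_path": rec.ident, "label": rec.label, "seed_tag": rec.seed_tag})
        pd.DataFrame(rows).to_csv(out / manifest, index=False)
        return out


def load_image_tree(root: str | Path) -> LabeledImageSet:
    """Load a class-per-folder image tree (PNG/TIFF/JPEG) from disk.

    Folders are visited in lexicographic order and files within each folder
    likewise, so a loaded set has a deterministic, reproducible order.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    records = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() not in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
                continue
            px = iio.imread(f)
            if px.ndim == 2:
                px = np.stack([px] * 3, axis=-1)
            if px.shape[2] == 4:
                px = px[:, :, :3]
            records.append(
                ImageRecord(
                    pixels=px.astype(np.uint8),
                    label=cls_dir.name,
                    source="file",
                    ident=str(f.relative_to(root)),
                )
            )
    if not records:
        raise ValueError(f"no images found under {root}")
    return LabeledImageSet(records)


class FeatureMatrix:
    """N x d matrix of per-sample feature vectors with aligned labels.

    ``provenance`` names the extraction route (``hcf``, ``stub``, ``hybrid``
    ...) and ``idents`` carries the per-row image identifiers used to verify
    alignment when matrices from different extractors are fused.
    """

    def __init__(
        self,
        values: np.ndarray,
        labels: Sequence[str],
        column_names: Sequence[str] | None = None,
        provenance: str = "",
        idents: Sequence[str] | None = None,
    ):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if values.shape[0] != len(labels):
            raise ValueError("row count must equal label count")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        self.values = values
        self.labels = list(labels)
        if column_names is None:
            column_names = [f"f{j}" for j in range(values.shape[1])]
        if len(column_names) != values.shape[1]:
            raise ValueError("column_names length must equal column count")
        self.column_names = list(column_names)
        self.provenance = provenance
        self.idents = list(idents) if idents is not None else [""] * values.shape[0]

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[:, idx],
            self.labels,
            [self.column_names[j] for j in idx],
            provenance=self.provenance,
            idents=self.idents,
        )

    def select_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[idx],
            [self.labels[i] for i in idx],
            self.column_names,
            provenance=self.provenance,
            idents=[self.idents[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "image_path", self.idents)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c not in ("image_path", "label")]
        return cls(
            df[cols].to_numpy(dtype=np.float64),
            df["label"].astype(str).tolist(),
            cols,
            provenance=provenance,
            idents=df["image_path"].astype(str).tolist() if "image_path" in df else None,
        )
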