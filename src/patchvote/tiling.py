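"""Segmentation-guided patch extraction with a dynamic stride.

The scanner slides a ``patch_size`` window over the image in row-major
order.  A candidate window is accepted when at least ``coverage_threshold``
of its area is covered by segmented nuclei and it does not overlap any
previously accepted window.  After an acceptance the column cursor jumps a
full patch size; after a rejection it advances by only
``fine_stride_fraction`` of the patch size (48 px at the default 480/0.10),
so nucleus-dense regions are tiled coarsely while sparse regions are
searched finely.  The row cursor advances analogously, driven by whether
the row produced any accepted patch.  Windows extending past the image
edge are skipped; no padding is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InvalidParameterError

DEFAULT_PATCH_SIZE = 480
DEFAULT_COVERAGE_THRESHOLD = 0.20
DEFAULT_FINE_STRIDE_FRACTION = 0.10


@dataclass(frozen=True)
class PatchBox:
    """Half-open window [row0, row0+size) x [col0, col0+size), 0-based."""

    row0: int
    col0: int
    size: int = DEFAULT_PATCH_SIZE

    def overlaps(self, other: "PatchBox") -> bool:
        return (self.row0 < other.row0 + other.size
                and other.row0 < self.row0 + self.size
                and self.col0 < other.col0 + other.size
                and other.col0 < self.col0 + self.size)


@dataclass
class PatchSet:
    """Accepted patches of one image, in deterministic scan order."""

    boxes: list[PatchBox] = field(default_factory=list)
    coverages: list[float] = field(default_factory=list)
    source_image_id: str = ""

    def __len__(self) -> int:
        return len(self.boxes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "image_id": [self.source_image_id] * len(self.boxes),
            "row0": [b.row0 for b in self.boxes],
            "col0": [b.col0 for b in self.boxes],
            "size": [b.size for b in self.boxes],
            "coverage": self.coverages,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, image_id: str | None = None) -> "PatchSet":
        if image_id is not None:
            frame = frame[frame["image_id"] == image_id]
        boxes = [PatchBox(int(r), int(c), int(s))
                 for r, c, s in zip(frame["row0"], frame["col0"], frame["size"])]
        ids = frame["image_id"].unique()
        return cls(boxes=boxes, coverages=[float(v) for v in frame["coverage"]],
                   source_image_id=str(ids[0]) if len(ids) else "")


def nuclei_coverage(mask: np.ndarray, box: PatchBox) -> float:
    """Fraction of the window covered by mask foreground."""
    mask = np.asarray(mask)
    h, w = mask.shape[:2]
    if (box.row0 < 0 or box.col0 < 0
            or box.row0 + box.size > h or box.col0 + box.size > w):
        raise InvalidParameterError(f"box {box} is out of bounds for {h}x{w} mask")
    window = mask[box.row0:box.row0 + box.size, box.col0:box.col0 + box.size]
    return float(np.count_nonzero(window)) / float(box.size * box.size)


def extract_patches(mask: np.ndarray,
                    patch_size: int = DEFAULT_PATCH_SIZE,
                    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                    fine_stride_fraction: float = DEFAULT_FINE_STRIDE_FRACTION,
                    image_id: str = "") -> PatchSet:
    """Dynamic-stride scan over a nuclei mask (see module docstring).

    A mask smaller than ``patch_size`` in either dimension yields an empty
    set.  The integral image of the mask makes each coverage query O(1).
    """
    if patch_size < 1:
        raise InvalidParameterError("patch_size must be >= 1")
    if not 0 < coverage_threshold <= 1:
        raise InvalidParameterError("coverage_threshold must lie in (0, 1]")
    if not 0 < fine_stride_fraction <= 1:
        raise InvalidParameterError("fine_stride_fraction must lie in (0, 1]")
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    out = PatchSet(source_image_id=image_id)
    if h < patch_size or w < patch_size:
        return out
    fine = max(1, int(round(fine_stride_fraction * patch_size)))
    area = float(patch_size * patch_size)
    # Integral image with a zero top row/left column.
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=integral[1:, 1:])

    def coverage_at(r: int, c: int) -> float:
        s = (integral[r + patch_size, c + patch_size] - integral[r, c + patch_size]
             - integral[r + patch_size, c] + integral[r, c])
        return float(s) / area

    row = 0
    while row + patch_size <= h:
        row_accepted = False
        col = 0
        while col + patch_size <= w:
            box = PatchBox(row, col, patch_size)
            cov = coverage_at(row, col)
            disjoint = all(not box.overlaps(b) for b in out.boxes)
            if cov >= coverage_threshold and disjoint:
                out.boxes.append(box)
                out.coverages.append(cov)
                row_accepted = True
                col += patch_size
            else:
                col += fine
        row += patch_size if row_accepted else fine
    return out


def crop_patches(image: np.ndarray, patches: PatchSet,
                 image_id: str | None = None) -> list[np.ndarray]:
    """Crop each accepted box out of the image, preserving patch order."""
    if image_id is not None and patches.source_image_id and image_id != patches.source_image_id:
        raise InvalidParameterError(
            f"image id {image_id!r} does not match patch set "
            f"{patches.source_image_id!r}")
    image = np.asarray(image)
    h, w = image.shape[:2]
    crops = []
    for box in patches.boxes:
        if box.row0 + box.size > h or box.col0 + box.size > w:
            raise InvalidParameterError(f"box {box} exceeds image bounds {h}x{w}")
        crops.append(image[box.row0:box.row0 + box.size,
                           box.col0:box.col0 + box.size])
    return crops


class PatchExtractor(BaseEstimator):
    """Dynamic-stride patch extractor (stateless scikit-learn estimator).

    Parameters mirror the scan rules: 480 px windows, 20% minimum nuclear
    coverage, 10% fine stride after a rejection.
    """

    def __init__(self, patch_size: int = DEFAULT_PATCH_SIZE,
                 coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                 fine_stride_fraction: float = DEFAULT_FINE_STRIDE_FRACTION):
        self.patch_size = patch_size
        self.coverage_threshold = coverage_threshold
        self.fine_stride_fraction = fine_stride_fraction

    def fit(self, X=None, y=None) -> "PatchExtractor":
        return self

    def extract(self, mask: np.ndarray, image: np.ndarray | None = None,
                image_id: str = "") -> PatchSet:
        if image is not None and np.asarray(image).shape[:2] != np.asarray(mask).shape[:2]:
            raise InvalidParameterError("image and mask dimensions disagree")
        return extract_patches(mask, self.patch_size, self.coverage_threshold,
                               self.fine_stride_fraction, image_id=image_id)
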