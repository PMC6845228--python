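"""Binary pixel masks for Purkinje-cell dendrite ROIs.

A :class:`PixelMask` is a set of (row, col) pixels with an integer id, the
unit ROI of the whole analysis: segmentation produces them, trace extraction
averages over them, and cross-session tracking matches them by overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PixelMask:
    """Binary dendrite ROI as explicit pixel coordinates (0-based, row-major)."""

    rows: np.ndarray
    cols: np.ndarray
    id: int = 0
    shape: tuple[int, int] | None = None  # image bounds, if known

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.shape != self.cols.shape:
            raise ValueError("rows and cols must have equal length")
        if self.shape is not None and self.area:
            if (
                self.rows.min() < 0
                or self.cols.min() < 0
                or self.rows.max() >= self.shape[0]
                or self.cols.max() >= self.shape[1]
            ):
                raise ValueError("mask pixels outside image bounds")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def linear_indices(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or self.shape
        if shape is None:
            raise ValueError("image shape required for linear indices")
        return self.rows * shape[1] + self.cols

    def to_bool(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or self.shape
        if shape is None:
            raise ValueError("image shape required")
        out = np.zeros(shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out

    @classmethod
    def from_bool(
        cls, image: np.ndarray, id: int = 0, shape: tuple[int, int] | None = None
    ) -> "PixelMask":
        rows, cols = np.nonzero(image)
        return cls(rows=rows, cols=cols, id=id, shape=shape or image.shape)

    def intersection_area(self, other: "PixelMask") -> int:
        shape = self.shape or other.shape
        if shape is None:
            raise ValueError("image shape required for intersection")
        a = set(map(int, self.linear_indices(shape)))
        b = set(map(int, other.linear_indices(shape)))
        return len(a & b)

    def aspect_ratio(self) -> float:
        """Principal-axis length/width ratio from second-order image moments."""
        r = self.rows - self.rows.mean()
        c = self.cols - self.cols.mean()
        cov = np.cov(np.stack([r, c]).astype(float))
        evals = np.sort(np.linalg.eigvalsh(cov))
        if evals[0] <= 0:
            return np.inf
        return float(np.sqrt(evals[1] / evals[0]))


def pairwise_disjoint(masks: list[PixelMask], shape: tuple[int, int]) -> bool:
    counts = np.zeros(shape[0] * shape[1], dtype=np.int32)
    for m in masks:
        counts[m.linear_indices(shape)] += 1
    return bool((counts <= 1).all())


def masks_to_label_image(masks: list[PixelMask], shape: tuple[int, int]) -> np.ndarray:
    """16-bit label image: 0 = background, k = mask with id k."""
    out = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        out[m.rows, m.cols] = m.id
    return out


def label_image_to_masks(label: np.ndarray) -> list[PixelMask]:
    masks = []
    for k in np.unique(label):
        if k == 0:
            continue
        masks.append(PixelMask.from_bool(label == k, id=int(k)))
    return masks
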