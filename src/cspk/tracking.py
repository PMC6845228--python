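"""Cross-session dendrite tracking by mask overlap.

The post-learning mean image is rigidly registered to the pre-learning
one; the resulting pixel shift is applied to the post-learning masks, and
mask pairs overlapping by more than 50% (of the smaller mask) are greedily
resolved into a one-to-one matching.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masks import PixelMask
from .preprocess import estimate_rigid_shift


@dataclass
class MatchResult:
    """One-to-one dendrite matching between two sessions."""

    pairs: list[tuple[int, int, float]]  # (pre_id, post_id, overlap_fraction)
    shift_applied: tuple[float, float] = (0.0, 0.0)
    unmatched_pre: list[int] = field(default_factory=list)
    unmatched_post: list[int] = field(default_factory=list)

    @property
    def matched_pre_ids(self) -> set[int]:
        return {p for p, _, _ in self.pairs}

    @property
    def matched_post_ids(self) -> set[int]:
        return {q for _, q, _ in self.pairs}


def register_sessions(
    mean_pre: np.ndarray, mean_post: np.ndarray, upsample: int = 20
) -> tuple[float, float]:
    """Rigid (dy, dx) translation aligning the post session onto the pre one.

    The returned shift is what must be applied to post-session content
    (masks, frames) to land it in pre-session coordinates.
    """
    dy, dx = estimate_rigid_shift(mean_post, mean_pre, upsample)
    return (-dy, -dx)


def shift_masks(
    masks: list[PixelMask], shift: tuple[float, float]
) -> list[PixelMask]:
    """Translate masks by the integer-rounded shift; pixels leaving the image
    are dropped, and masks emptied entirely are dropped."""
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    out = []
    for m in masks:
        if m.shape is None:
            raise ValueError("mask image shape required for shifting")
        rows = m.rows + dy
        cols = m.cols + dx
        keep = (rows >= 0) & (rows < m.shape[0]) & (cols >= 0) & (cols < m.shape[1])
        if not keep.any():
            continue
        out.append(PixelMask(rows=rows[keep], cols=cols[keep], id=m.id, shape=m.shape))
    return out


def overlap_fraction(a: PixelMask, b: PixelMask) -> float:
    """|a ∩ b| / min(|a|, |b|): the most permissive symmetric convention."""
    if a.area == 0 or b.area == 0:
        raise ValueError("overlap undefined for empty masks")
    return a.intersection_area(b) / min(a.area, b.area)


def match_dendrites(
    pre_masks: list[PixelMask],
    post_masks_shifted: list[PixelMask],
    min_overlap: float = 0.5,
) -> MatchResult:
    """Match masks across sessions at > ``min_overlap`` overlap.

    Candidate pairs above the threshold are resolved into a one-to-one
    matching greedily by descending overlap, ties broken by (pre_id,
    post_id); the result is independent of input ordering.
    """
    candidates = []
    for a in pre_masks:
        for b in post_masks_shifted:
            f = overlap_fraction(a, b)
            if f > min_overlap:
                candidates.append((f, a.id, b.id))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs = []
    for f, pid, qid in candidates:
        if pid in used_pre or qid in used_post:
            continue
        pairs.append((pid, qid, f))
        used_pre.add(pid)
        used_post.add(qid)
    return MatchResult(
        pairs=pairs,
        unmatched_pre=sorted(m.id for m in pre_masks if m.id not in used_pre),
        unmatched_post=sorted(m.id for m in post_masks_shifted if m.id not in used_post),
    )


def overlap_image(
    pre_masks: list[PixelMask],
    post_masks: list[PixelMask],
    shape: tuple[int, int],
) -> np.ndarray:
    """RGB overlay: pre masks red, post masks green, overlap yellow."""
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    for m in pre_masks:
        rgb[m.rows, m.cols, 0] = 255
    for m in post_masks:
        rgb[m.rows, m.cols, 1] = 255
    return rgb
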