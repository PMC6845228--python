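"""Minimal figure helpers: PSTHs with SEM bands and mask overlays."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .masks import PixelMask
from .responses import Psth


def plot_psth(
    psth: Psth,
    ax=None,
    color: str = "k",
    label: str | None = None,
    reward_time: float | None = 0.6,
):
    """Mean Cspk rate ± SEM across dendrites, aligned to the cue (or other
    alignment event); dashed line marks reward delivery."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.fill_between(
        psth.bin_centers,
        psth.mean_rate - psth.sem,
        psth.mean_rate + psth.sem,
        alpha=0.3,
        color=color,
        linewidth=0,
    )
    ax.plot(psth.bin_centers, psth.mean_rate, color=color, label=label)
    ax.axvline(0.0, color="0.6", linestyle=":", linewidth=1)
    if reward_time is not None:
        ax.axvline(reward_time, color="0.6", linestyle="--", linewidth=1)
    ax.set_xlabel(f"time from {psth.alignment} (s)")
    ax.set_ylabel("Cspk rate (Hz)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_mask_overlay(
    pre_masks: list[PixelMask],
    post_masks: list[PixelMask],
    shape: tuple[int, int],
    ax=None,
):
    """Pre-session masks red, post-session green, overlap yellow."""
    from .tracking import overlap_image

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    ax.imshow(overlap_image(pre_masks, post_masks, shape))
    ax.set_axis_off()
    return ax
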