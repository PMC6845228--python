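"""Complex-spike event detection and trial alignment.

Cspk events are extracted from raw fluorescence traces by thresholding the
one-frame first derivative at ``threshold_sd`` (default 1.7) standard
deviations above its baseline mean, where the baseline is the set of
inter-trial-interval frames.  Each maximal suprathreshold run yields one
event at its first frame; events separated by at least one sub-threshold
frame are counted separately.

Detection runs on raw fluorescence, not dF/F: the derivative threshold is
invariant to additive offsets and positive rescaling of the trace, so
per-trial normalization would add nothing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """Baseline derivative has zero variance; no threshold can be formed."""


@dataclass
class EventTrain:
    """Detected (or planted) Cspk event frame indices for one dendrite."""

    frames: np.ndarray
    frame_rate: float
    dendrite_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if self.frames.size > 1 and not (np.diff(self.frames) >= 2).all():
            raise ValueError(
                "event frames must be strictly increasing with >= 1 intervening frame"
            )

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.frame_rate

    @classmethod
    def from_times(
        cls, times: np.ndarray, frame_rate: float, dendrite_id: int = 0
    ) -> "EventTrain":
        """Quantize event times to frames, merging events landing < 2 frames apart."""
        frames = np.unique(np.floor(np.asarray(times) * frame_rate).astype(np.int64))
        keep = []
        for f in frames:
            if not keep or f - keep[-1] >= 2:
                keep.append(int(f))
        return cls(frames=np.asarray(keep), frame_rate=frame_rate, dendrite_id=dendrite_id)


def iti_frames(
    trials: pd.DataFrame,
    n_frames: int,
    frame_rate: float,
    reward_delay: float = 0.6,
    post_reward_pad: float = 1.0,
) -> np.ndarray:
    """Frame indices outside all cue -> reward + 1 s trial windows (the baseline)."""
    keep = np.ones(n_frames, dtype=bool)
    t = np.arange(n_frames) / frame_rate
    from .synth import trial_slot_times

    for s in trial_slot_times(trials, reward_delay):
        keep &= ~((t >= s) & (t <= s + reward_delay + post_reward_pad))
    return np.nonzero(keep)[0]


def detect_events(
    trace: np.ndarray,
    baseline_frames: np.ndarray,
    threshold_sd: float = 1.7,
    frame_rate: float = 30.0,
    dendrite_id: int = 0,
) -> EventTrain:
    """Detect Cspk events via the derivative-threshold rule.

    ``d[t] = trace[t+1] - trace[t]``; the threshold is
    ``mean(d[baseline]) + threshold_sd * SD(d[baseline])``; one event is
    recorded at the first frame of each maximal suprathreshold run.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 frames")
    baseline_frames = np.asarray(baseline_frames, dtype=np.intp)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames must be non-empty")

    d = np.diff(trace)
    base = baseline_frames[baseline_frames < d.size]
    mu = d[base].mean()
    sd = d[base].std()
    if sd == 0:
        raise DegenerateBaselineError("zero baseline derivative variance")
    above = d > mu + threshold_sd * sd
    # run starts: above[t] and not above[t-1]
    starts = np.nonzero(above & ~np.concatenate([[False], above[:-1]]))[0]
    return EventTrain(frames=starts, frame_rate=frame_rate, dendrite_id=dendrite_id)


@dataclass
class Raster:
    """Trial x relative-frame binary event indicator."""

    matrix: np.ndarray  # (n_trials_kept, n_bins) uint8
    window: tuple[float, float]
    alignment: str
    frame_rate: float
    trial_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    n_skipped: int = 0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def first_rel_frame(self) -> int:
        return int(np.floor(self.window[0] * self.frame_rate + 1e-9))

    @property
    def bin_left_edges(self) -> np.ndarray:
        return (self.first_rel_frame + np.arange(self.n_bins)) / self.frame_rate

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left_edges + 0.5 / self.frame_rate


def alignment_times(
    trials: pd.DataFrame, alignment: str, licks: np.ndarray | None = None
) -> np.ndarray:
    if alignment == "cue":
        return trials["cue_onset"].to_numpy(dtype=float)
    if alignment == "reward":
        return trials["reward_time"].to_numpy(dtype=float)
    if alignment == "lick":
        if licks is None:
            raise ValueError("lick alignment requires lick times")
        return np.asarray(licks, dtype=float)
    raise ValueError(f"unknown alignment {alignment!r}")


def event_raster(
    events: EventTrain,
    trials: pd.DataFrame,
    alignment: str = "cue",
    window: tuple[float, float] = (-2.0, 2.0),
    align_times: np.ndarray | None = None,
) -> Raster:
    """Bin events into a trial x relative-frame binary raster.

    An event at frame f is assigned relative frame
    ``floor((f / frame_rate - t_align) * frame_rate)``.  Trials whose
    alignment time is absent (e.g. the cue on unexpected-reward trials)
    are skipped and counted in ``n_skipped``.
    """
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("window_start must be < window_end")
    fr = events.frame_rate
    if align_times is None:
        align_times = alignment_times(trials, alignment)
    align_times = np.asarray(align_times, dtype=float)
    valid = ~np.isnan(align_times)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("event_raster: skipped %d trials without %s time", n_skipped, alignment)
    kept_idx = np.nonzero(valid)[0]

    first = int(np.floor(w0 * fr + 1e-9))
    n_bins = int(round((w1 - w0) * fr))
    mat = np.zeros((kept_idx.size, n_bins), dtype=np.uint8)
    ev_t = events.times
    for row, i in enumerate(kept_idx):
        rel = np.floor((ev_t - align_times[i]) * fr + 1e-9).astype(int) - first
        rel = rel[(rel >= 0) & (rel < n_bins)]
        mat[row, rel] = 1
    return Raster(
        matrix=mat,
        window=window,
        alignment=alignment,
        frame_rate=fr,
        trial_index=kept_idx,
        n_skipped=n_skipped,
    )
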