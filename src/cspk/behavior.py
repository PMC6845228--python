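"""Behavioral metrics of the conditioning task.

Reaction time is the first lick 200-1000 ms after cue onset; miss rate is
the fraction of cue trials with no lick in the 1 s after the cue; the
learning criterion requires mean reaction time < 650 ms and miss rate
< 15%, plus stabilization across sessions.  All windows follow the
package-wide half-open convention: lower bound exclusive, upper inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RT_WINDOW = (0.200, 1.000)  # s after cue onset
MISS_WINDOW = (0.0, 1.0)
RT_THRESHOLD = 0.650
MISS_THRESHOLD = 0.15


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. no cue-bearing trials)."""


def _check_sorted(licks: np.ndarray) -> np.ndarray:
    licks = np.asarray(licks, dtype=float)
    if licks.size > 1 and (np.diff(licks) < 0).any():
        raise ValueError("lick times must be sorted")
    if licks.size and licks[0] < 0:
        raise ValueError("lick times must be non-negative")
    return licks


def reaction_time(licks: np.ndarray, cue_onset: float) -> float | None:
    """First lick in (cue + 0.2, cue + 1.0], relative to cue; None if absent."""
    licks = _check_sorted(licks)
    if not np.isfinite(cue_onset):
        raise ValueError("cue_onset must be finite")
    lo, hi = cue_onset + RT_WINDOW[0], cue_onset + RT_WINDOW[1]
    hits = licks[(licks > lo) & (licks <= hi)]
    return float(hits[0] - cue_onset) if hits.size else None


def miss_rate(trials: pd.DataFrame, licks: np.ndarray) -> float:
    """Fraction of cue-bearing trials with zero licks in (cue, cue + 1 s]."""
    licks = _check_sorted(licks)
    cues = trials["cue_onset"].to_numpy(dtype=float)
    cues = cues[~np.isnan(cues)]
    if cues.size == 0:
        raise UndefinedMetricError("no cue-bearing trials")
    misses = 0
    for c in cues:
        if not ((licks > c + MISS_WINDOW[0]) & (licks <= c + MISS_WINDOW[1])).any():
            misses += 1
    return misses / cues.size


def first_lick_bout(
    licks: np.ndarray, cue_onset: float, min_licks: int = 3, span: float = 0.300
) -> float | None:
    """Onset (relative to cue) of the first lick bout after the cue.

    A bout starts at the earliest lick L > cue with at least ``min_licks``
    licks within ``span`` of L (strictly: in [L, L + span)); None when no
    such lick exists.
    """
    licks = _check_sorted(licks)
    after = licks[licks > cue_onset]
    for i in range(after.size):
        n_in = np.count_nonzero(
            (after >= after[i]) & (after - after[i] < span)
        )
        if n_in >= min_licks:
            return float(after[i] - cue_onset)
    return None


@dataclass
class BehaviorSummary:
    """Per-session behavioral metrics."""

    mean_reaction_time: float
    miss_rate: float
    n_trials: int
    lick_psth: np.ndarray | None = None
    lick_psth_bins: np.ndarray | None = None


def learning_met(
    summaries: list[BehaviorSummary],
    rt_threshold: float = RT_THRESHOLD,
    miss_threshold: float = MISS_THRESHOLD,
    stabilization_tol: float = 0.10,
) -> bool:
    """Learning criterion: latest session RT < 650 ms, miss rate < 15%,
    and reaction times stabilized (latest two sessions' mean RTs differ by
    less than ``stabilization_tol`` relative to the earlier one).

    A single session cannot demonstrate stabilization and returns False.
    """
    if not summaries:
        raise ValueError("at least one session required")
    latest = summaries[-1]
    if not (latest.mean_reaction_time < rt_threshold and latest.miss_rate < miss_threshold):
        return False
    if len(summaries) < 2:
        return False
    prev = summaries[-2]
    if prev.mean_reaction_time <= 0:
        return False
    rel = abs(latest.mean_reaction_time - prev.mean_reaction_time) / prev.mean_reaction_time
    return rel < stabilization_tol


def lick_psth(
    licks: np.ndarray,
    trials: pd.DataFrame,
    bin_s: float = 0.1,
    window: tuple[float, float] = (-1.0, 3.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Cue-aligned mean lick rate (Hz per bin); returns (rates, bin_centers).

    A lick at relative time t falls in bin i when
    window[0] + i*bin < t <= window[0] + (i+1)*bin.
    """
    if bin_s <= 0:
        raise ValueError("bin must be positive")
    licks = _check_sorted(licks)
    cues = trials["cue_onset"].to_numpy(dtype=float)
    cues = cues[~np.isnan(cues)]
    n_bins = int(round((window[1] - window[0]) / bin_s))
    counts = np.zeros(n_bins)
    for c in cues:
        rel = licks - c
        rel = rel[(rel > window[0]) & (rel <= window[1])]
        idx = np.ceil((rel - window[0]) / bin_s - 1e-9).astype(int) - 1
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    n = max(cues.size, 1)
    centers = window[0] + (np.arange(n_bins) + 0.5) * bin_s
    return counts / (n * bin_s), centers


def summarize(
    trials: pd.DataFrame,
    licks: np.ndarray,
    bin_s: float = 0.1,
    window: tuple[float, float] = (-1.0, 3.0),
) -> BehaviorSummary:
    """Compute the session's behavioral summary (RT, miss rate, lick PSTH)."""
    cues = trials["cue_onset"].to_numpy(dtype=float)
    cues = cues[~np.isnan(cues)]
    rts = [reaction_time(licks, c) for c in cues]
    rts = [r for r in rts if r is not None]
    rates, centers = lick_psth(licks, trials, bin_s, window)
    return BehaviorSummary(
        mean_reaction_time=float(np.mean(rts)) if rts else float("nan"),
        miss_rate=miss_rate(trials, licks),
        n_trials=int(cues.size),
        lick_psth=rates,
        lick_psth_bins=centers,
    )
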