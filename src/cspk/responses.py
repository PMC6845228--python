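"""PSTH construction and response statistics.

Implements the full set of trial-aligned statistics used to characterise
complex-spike responses: population and per-dendrite peri-stimulus time
histograms, peak-centred 100 ms window rates, the paired one-tailed
population t-test against a 1200 ms baseline-window peak, the
1-SD/two-consecutive-frame responsiveness and suppression classifiers,
lick-triggered averages from isolated inter-trial licks, trial segregation
by lick latency/rate quartiles or movement deciles, and PSTH peak latency.

Population uncertainty is SEM across dendrites, not trials, and no
multiple-comparison correction is applied anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import first_lick_bout
from .events import EventTrain, Raster, event_raster
from .synth import PiezoTrace, trial_slot_times

PEAK_WINDOW_S = 0.100  # analysis window centred on the PSTH peak
BASELINE_WINDOW_S = 1.200  # pre-cue window searched for the baseline peak


class InsufficientLicksError(RuntimeError):
    """Fewer than the required number of qualifying ITI licks (exclusion)."""


class MetricUnavailableError(ValueError):
    """Segregation metric missing on too many trials."""


@dataclass
class Psth:
    """Mean event rate (Hz) per bin relative to an alignment event."""

    bin_centers: np.ndarray
    mean_rate: np.ndarray
    sem: np.ndarray
    n_trials: int
    n_dendrites: int
    frame_rate: float
    alignment: str = "cue"

    @property
    def bin_width(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class WindowSpec:
    """Named analysis window with bounds relative to the alignment event."""

    kind: str
    bounds: tuple[float, float]

    @classmethod
    def pre_reward(cls, reward_delay: float = 0.6) -> "WindowSpec":
        """The 600 ms between cue onset and reward delivery (cue-aligned)."""
        return cls("pre_reward", (0.0, reward_delay))

    @classmethod
    def post_reward(cls, reward_delay: float = 0.6) -> "WindowSpec":
        """The 600 ms after (expected) reward, cue-aligned."""
        return cls("post_reward", (reward_delay, 2 * reward_delay))

    @classmethod
    def post_reward_reward_aligned(cls, reward_delay: float = 0.6) -> "WindowSpec":
        return cls("post_reward", (0.0, reward_delay))

    @classmethod
    def pre_cue_baseline(cls, length: float = 2.0) -> "WindowSpec":
        return cls("pre_cue_baseline", (-length, 0.0))

    @classmethod
    def baseline_1200ms(cls) -> "WindowSpec":
        return cls("baseline_1200ms", (-BASELINE_WINDOW_S, 0.0))


def _window_bins(bin_centers: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Bin indices whose centers fall in (lo, hi] (global bound convention)."""
    lo, hi = bounds
    idx = np.nonzero((bin_centers > lo) & (bin_centers <= hi))[0]
    return idx


def dendrite_rates(rasters: list[Raster]) -> np.ndarray:
    """Per-dendrite PSTH matrix (dendrites x bins), Hz."""
    if not rasters:
        raise ValueError("no rasters")
    fr = rasters[0].frame_rate
    rows = []
    for r in rasters:
        if r.matrix.shape[0] == 0:
            raise ValueError("raster with zero trials")
        rows.append(r.matrix.mean(axis=0) * fr)
    return np.stack(rows)


def build_psth(rasters: list[Raster]) -> tuple[Psth, np.ndarray]:
    """Population PSTH (mean ± SEM across dendrites) and per-dendrite rates."""
    rates = dendrite_rates(rasters)
    r0 = rasters[0]
    n_d = rates.shape[0]
    sem = (
        rates.std(axis=0, ddof=1) / np.sqrt(n_d) if n_d > 1 else np.zeros(rates.shape[1])
    )
    pop = Psth(
        bin_centers=r0.bin_centers,
        mean_rate=rates.mean(axis=0),
        sem=sem,
        n_trials=int(r0.matrix.shape[0]),
        n_dendrites=n_d,
        frame_rate=r0.frame_rate,
        alignment=r0.alignment,
    )
    return pop, rates


def peak_window_rates(
    rates: np.ndarray,
    pop: Psth,
    window: WindowSpec,
    peak_window_s: float = PEAK_WINDOW_S,
) -> tuple[np.ndarray, float]:
    """Per-dendrite mean rate in the 100 ms window centred on the population
    PSTH peak within ``window``; ties broken toward the earliest bin; the
    100 ms window is clipped at the analysis-window edge.

    Returns (per-dendrite rates, peak time).
    """
    idx = _window_bins(pop.bin_centers, window.bounds)
    if idx.size == 0:
        raise ValueError(f"window {window.bounds} outside the PSTH span")
    peak_bin = idx[int(np.argmax(pop.mean_rate[idx]))]  # argmax: earliest tie wins
    peak_t = float(pop.bin_centers[peak_bin])
    half = peak_window_s / 2.0
    lo = max(peak_t - half, window.bounds[0])
    hi = min(peak_t + half, window.bounds[1])
    sel = np.nonzero((pop.bin_centers >= lo - 1e-9) & (pop.bin_centers <= hi + 1e-9))[0]
    sel = np.intersect1d(sel, idx)
    return rates[:, sel].mean(axis=1), peak_t


@dataclass
class PopulationTest:
    t: float
    p: float
    n: int
    degenerate: bool = False


def population_response_test(
    rates_at_peak: np.ndarray, rates_at_baseline_peak: np.ndarray
) -> PopulationTest:
    """Paired one-tailed t-test across dendrites: peak rate > baseline peak.

    All-zero differences are degenerate (no variability to test); a
    zero-variance but non-zero difference yields p = 0 or 1 by sign.
    """
    a = np.asarray(rates_at_peak, dtype=float)
    b = np.asarray(rates_at_baseline_peak, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors with n >= 2 required")
    d = a - b
    if np.allclose(d, 0):
        return PopulationTest(t=np.nan, p=np.nan, n=a.size, degenerate=True)
    if np.allclose(d.std(ddof=1), 0):
        p = 0.0 if d.mean() > 0 else 1.0
        return PopulationTest(t=np.inf if p == 0 else -np.inf, p=p, n=a.size)
    res = stats.ttest_rel(a, b, alternative="greater")
    return PopulationTest(t=float(res.statistic), p=float(res.pvalue), n=a.size)


def baseline_peak_rates(
    rates: np.ndarray, pop: Psth, peak_window_s: float = PEAK_WINDOW_S
) -> tuple[np.ndarray, float]:
    """Peak-centred rates within the 1200 ms pre-cue baseline window."""
    return peak_window_rates(rates, pop, WindowSpec.baseline_1200ms(), peak_window_s)


def classify_event_responsive(
    rates: np.ndarray,
    bin_centers: np.ndarray,
    window: WindowSpec,
    baseline: WindowSpec | None = None,
    n_consecutive: int = 2,
    n_sd: float = 1.0,
) -> np.ndarray:
    """Event-responsive flags: >= 2 consecutive bins in the window exceed the
    dendrite's pre-cue mean + 1 SD (both computed over its pre-cue bins)."""
    baseline = baseline or WindowSpec.pre_cue_baseline()
    rates = np.atleast_2d(rates)
    wi = _window_bins(bin_centers, window.bounds)
    bi = _window_bins(bin_centers, baseline.bounds)
    if bi.size < 2:
        raise ValueError("baseline window needs at least 2 bins")
    mu = rates[:, bi].mean(axis=1)
    sd = rates[:, bi].std(axis=1)
    above = rates[:, wi] > (mu + n_sd * sd)[:, None]
    return _has_consecutive(above, n_consecutive)


def classify_suppressed(
    rates: np.ndarray,
    bin_centers: np.ndarray,
    post_window: WindowSpec,
    baseline: WindowSpec | None = None,
    pre_reward: WindowSpec | None = None,
    n_consecutive: int = 2,
    n_sd: float = 1.0,
) -> np.ndarray:
    """Suppressed flags: >= 2 consecutive post-reward bins below BOTH the
    pre-cue mean - 1 SD and the pre-reward mean - 1 SD."""
    baseline = baseline or WindowSpec.pre_cue_baseline()
    pre_reward = pre_reward or WindowSpec.pre_reward()
    rates = np.atleast_2d(rates)
    wi = _window_bins(bin_centers, post_window.bounds)
    bi = _window_bins(bin_centers, baseline.bounds)
    pi = _window_bins(bin_centers, pre_reward.bounds)
    mu_b = rates[:, bi].mean(axis=1) - n_sd * rates[:, bi].std(axis=1)
    mu_p = rates[:, pi].mean(axis=1) - n_sd * rates[:, pi].std(axis=1)
    below = (rates[:, wi] < mu_b[:, None]) & (rates[:, wi] < mu_p[:, None])
    return _has_consecutive(below, n_consecutive)


def _has_consecutive(flags: np.ndarray, n: int) -> np.ndarray:
    if flags.shape[1] < n:
        return np.zeros(flags.shape[0], dtype=bool)
    run = np.ones(flags.shape, dtype=bool)[:, : flags.shape[1] - n + 1]
    for k in range(n):
        run &= flags[:, k : flags.shape[1] - n + 1 + k]
    return run.any(axis=1)


@dataclass
class LickTriggeredResult:
    psth: Psth
    p: float
    peak_time: float
    n_licks: int


def isolated_iti_licks(
    licks: np.ndarray,
    trials: pd.DataFrame,
    reward_delay: float = 0.6,
    isolation_s: float = 0.250,
    trial_pad_s: float = 2.0,
) -> np.ndarray:
    """Single ITI licks separated by >= 250 ms from their neighbours."""
    licks = np.asarray(licks, dtype=float)
    keep = np.ones(licks.size, dtype=bool)
    if licks.size > 1:
        gap_prev = np.diff(licks, prepend=-np.inf)
        gap_next = np.diff(licks, append=np.inf)
        keep &= (gap_prev >= isolation_s) & (gap_next >= isolation_s)
    for s in trial_slot_times(trials, reward_delay):
        keep &= ~((licks >= s) & (licks <= s + reward_delay + trial_pad_s))
    return licks[keep]


def lick_triggered_average(
    event_trains: list[EventTrain],
    licks: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-1.0, 1.0),
    min_licks: int = 4,
    reward_delay: float = 0.6,
    flank_s: float = 0.250,
) -> LickTriggeredResult:
    """Lick-triggered Cspk average from isolated ITI licks.

    The peak is identified within the five frames centred on the lick; its
    amplitude is compared (paired, one-tailed, across dendrites) with the
    mean of the two frames 250 ms before and the two frames 250 ms after
    the lick.  Experiments with fewer than four qualifying licks raise
    :class:`InsufficientLicksError`.
    """
    qual = isolated_iti_licks(licks, trials, reward_delay)
    if qual.size < min_licks:
        raise InsufficientLicksError(
            f"only {qual.size} qualifying ITI licks (need {min_licks})"
        )
    rasters = [
        event_raster(ev, trials, alignment="lick", window=window, align_times=qual)
        for ev in event_trains
    ]
    pop, rates = build_psth(rasters)
    fr = pop.frame_rate
    centers = pop.bin_centers
    # five frames centred on the lick: relative frames -2..2
    peak_sel = _window_bins(centers, (-2.5 / fr, 2.5 / fr))
    peak_bin = peak_sel[int(np.argmax(pop.mean_rate[peak_sel]))]
    peak_t = float(centers[peak_bin])
    flank_frames = int(round(flank_s * fr))
    flank_idx = []
    for off in (-flank_frames - 1, -flank_frames, flank_frames, flank_frames + 1):
        j = np.argmin(np.abs(centers - off / fr))
        flank_idx.append(int(j))
    flank_idx = sorted(set(flank_idx))
    peak_amp = rates[:, peak_bin]
    flank_amp = rates[:, flank_idx].mean(axis=1)
    test = population_response_test(peak_amp, flank_amp)
    p = 1.0 if test.degenerate else test.p
    return LickTriggeredResult(psth=pop, p=p, peak_time=peak_t, n_licks=int(qual.size))


@dataclass
class TrialSegregation:
    """Trial subsets selected by a per-trial metric."""

    metric: pd.Series  # indexed by trial number; NaN when undefined
    low: np.ndarray  # trial numbers: earliest latency / lowest rate / least movement
    high: np.ndarray
    by: str


def segregate_trials(
    trials: pd.DataFrame,
    licks: np.ndarray | None = None,
    piezo: PiezoTrace | None = None,
    by: str = "lick_latency_quartiles",
    reward_delay: float = 0.6,
    lick_rate_window: float = 1.0,
) -> TrialSegregation:
    """Segregate trials by lick latency quartiles, post-reward lick-rate
    quartiles, or pre-reward movement deciles.

    The metric must be defined on more than half the trials; ties at a
    boundary are resolved by trial index (stable sort).
    """
    values = {}
    if by == "lick_latency_quartiles":
        if licks is None:
            raise ValueError("licks required")
        for _, tr in trials.iterrows():
            if np.isnan(tr["cue_onset"]):
                continue
            values[int(tr["trial"])] = first_lick_bout(licks, tr["cue_onset"])
        frac = 4
    elif by == "lick_rate_quartiles":
        if licks is None:
            raise ValueError("licks required")
        licks = np.asarray(licks, dtype=float)
        for _, tr in trials.iterrows():
            rew = tr["reward_time"]
            if np.isnan(rew):
                continue
            n = np.count_nonzero((licks > rew) & (licks <= rew + lick_rate_window))
            values[int(tr["trial"])] = n / lick_rate_window
        frac = 4
    elif by == "movement_deciles":
        if piezo is None:
            raise ValueError("piezo trace required")
        slots = trial_slot_times(trials, reward_delay)
        for (_, tr), s in zip(trials.iterrows(), slots):
            values[int(tr["trial"])] = piezo.rms(s, s + reward_delay)
        frac = 10
    else:
        raise ValueError(f"unknown segregation mode {by!r}")

    metric = pd.Series(values, dtype=float).sort_index()
    defined = metric.dropna()
    if len(defined) <= len(metric) / 2 or len(defined) == 0:
        raise MetricUnavailableError(
            f"metric defined on {len(defined)}/{len(metric)} trials"
        )
    order = defined.index.to_numpy()[np.argsort(defined.to_numpy(), kind="stable")]
    k = max(1, len(defined) // frac)
    return TrialSegregation(
        metric=metric, low=order[:k], high=order[-k:][::-1], by=by
    )


def psth_latency(pop: Psth, window: WindowSpec | tuple[float, float]) -> float:
    """Time (bin centre, relative to alignment) of the maximum mean rate
    within the window; equal peaks resolve to the earlier bin."""
    bounds = window.bounds if isinstance(window, WindowSpec) else window
    idx = _window_bins(pop.bin_centers, bounds)
    if idx.size == 0:
        raise ValueError(f"window {bounds} outside PSTH span")
    return float(pop.bin_centers[idx[int(np.argmax(pop.mean_rate[idx]))]])
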