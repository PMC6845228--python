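"""Synthetic conditioning-session generator with known ground truth.

Generates everything the analysis consumes — trial tables, lick trains,
per-dendrite complex-spike (Cspk) event trains, GCaMP6f-like fluorescence
traces, dendritic fields of view, imaging movies with rigid motion, and
piezo movement traces — with every planted quantity recorded in a
:class:`GroundTruth` object so downstream stages can be validated without
any recorded data.

The statistical structure mirrors an appetitive classical-conditioning
task: a 100 ms visual cue, reward 600 ms after cue onset, 24-30 s
inter-trial intervals, and 20% special (reward-omission or
unexpected-reward) trials.  Regime presets plant the trial-locked Cspk
rate structure observed in lobule simplex, Crus I and Crus II before and
after learning: e.g. a post-reward rate bump in naive lobule simplex that
is replaced after training by a cue-locked bump preceding reward on both
rewarded and omission trials.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SessionConfig, ConfigurationError
from .masks import PixelMask, pairwise_disjoint

TRIAL_COLUMNS = ["trial", "cue_onset", "reward_time", "trial_type"]

#: seconds of quiet recording before the first trial and after the last one
LEAD_IN_S = 5.0
TAIL_S = 5.0
#: seconds after reward that still belong to the trial (consumption period)
POST_REWARD_S = 1.0


class PlacementError(RuntimeError):
    """Raised when dendrite masks cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def generate_trials(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one session's trial timeline.

    Inter-trial intervals are uniform over ``config.iti_range``; the number
    of special trials is ``round(fraction * n_trials)``, their positions
    drawn without replacement.  ``cue_onset`` is NaN on unexpected-reward
    trials and ``reward_time`` is NaN on omission trials; the underlying
    trial slot still occupies its place in the timeline.
    """
    config.validate()
    n = config.n_trials
    if n == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)

    n_special = int(round(config.special_trial_fraction * n))
    if config.special_trial_kind == "none":
        n_special = 0
    special = set(rng.choice(n, size=n_special, replace=False).tolist())

    span = config.reward_delay_from_cue + POST_REWARD_S
    itis = rng.uniform(*config.iti_range, size=n)

    rows = []
    t = LEAD_IN_S
    for i in range(n):
        cue = t
        reward = t + config.reward_delay_from_cue
        if i in special and config.special_trial_kind == "omission":
            rows.append((i, cue, np.nan, "omission"))
        elif i in special and config.special_trial_kind == "unexpected_reward":
            rows.append((i, np.nan, reward, "unexpected_reward"))
        else:
            rows.append((i, cue, reward, "rewarded"))
        t += span + itis[i]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trial_slot_times(trials: pd.DataFrame, reward_delay: float) -> np.ndarray:
    """Nominal cue-slot time per trial (reward_time - delay where cue absent)."""
    cue = trials["cue_onset"].to_numpy(dtype=float)
    rew = trials["reward_time"].to_numpy(dtype=float)
    slot = np.where(np.isnan(cue), rew - reward_delay, cue)
    return slot


def session_duration(trials: pd.DataFrame, config: SessionConfig) -> float:
    if len(trials) == 0:
        return LEAD_IN_S + TAIL_S
    slot = trial_slot_times(trials, config.reward_delay_from_cue)
    return float(slot[-1] + config.reward_delay_from_cue + POST_REWARD_S + TAIL_S)


# ---------------------------------------------------------------------------
# licking
# ---------------------------------------------------------------------------

@dataclass
class LickParams:
    """Lick-model parameters for one training stage.

    Reaction times are truncated-normal draws; a lick bout (>= 3 licks
    within 300 ms) begins at cue + reaction time on non-miss trials.
    """

    rt_mean: float = 0.74
    rt_sd: float = 0.12
    miss_prob: float = 0.39
    rt_bounds: tuple[float, float] = (0.25, 0.98)
    bout_extra_licks_mean: float = 3.0
    bout_ipi_range: tuple[float, float] = (0.08, 0.14)
    iti_lick_rate: float = 0.1
    unexpected_reward_delay: tuple[float, float] = (0.10, 0.30)

    @classmethod
    def naive(cls) -> "LickParams":
        return cls(rt_mean=0.74, rt_sd=0.12, miss_prob=0.39)

    @classmethod
    def trained(cls) -> "LickParams":
        return cls(rt_mean=0.54, rt_sd=0.08, miss_prob=0.03)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_licks(
    trials: pd.DataFrame,
    stage: str,
    params: LickParams | None = None,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
    reward_delay: float = 0.6,
) -> np.ndarray:
    """Generate a session lick train (sorted times, seconds).

    On non-miss cue trials a bout starts at cue + reaction time; on
    unexpected-reward trials a bout follows the reward itself.  Isolated
    licks are also emitted during the ITI at ``params.iti_lick_rate`` Hz.
    """
    if stage not in ("naive", "trained"):
        raise ConfigurationError(f"unknown stage {stage!r}")
    if params is None:
        params = LickParams.naive() if stage == "naive" else LickParams.trained()
    rng = np.random.default_rng() if rng is None else rng

    licks: list[float] = []

    def emit_bout(onset: float) -> None:
        n = 3 + rng.poisson(params.bout_extra_licks_mean)
        ipis = rng.uniform(*params.bout_ipi_range, size=n - 1)
        licks.extend(onset + np.concatenate([[0.0], np.cumsum(ipis)]))

    for _, tr in trials.iterrows():
        cue, rew = tr["cue_onset"], tr["reward_time"]
        if not np.isnan(cue):
            if rng.random() >= params.miss_prob:
                rt = float(
                    _truncnorm(rng, params.rt_mean, params.rt_sd, *params.rt_bounds)
                )
                emit_bout(cue + rt)
        elif not np.isnan(rew):  # unexpected reward: licking follows delivery
            emit_bout(rew + rng.uniform(*params.unexpected_reward_delay))

    if duration is None:
        slot = trial_slot_times(trials, reward_delay)
        duration = float(slot[-1] + reward_delay + POST_REWARD_S + TAIL_S) if len(trials) else LEAD_IN_S

    if params.iti_lick_rate > 0 and duration > 0:
        n_iti = rng.poisson(params.iti_lick_rate * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_iti))
        slot = trial_slot_times(trials, reward_delay)
        keep = np.ones(cand.size, dtype=bool)
        for s in slot:
            keep &= ~((cand >= s) & (cand <= s + reward_delay + 2.0))
        licks.extend(cand[keep])

    return np.sort(np.asarray(licks, dtype=float))


# ---------------------------------------------------------------------------
# Cspk rate profiles and event trains
# ---------------------------------------------------------------------------

@dataclass
class Bump:
    """One trial-locked rate elevation.

    ``center`` is relative to the alignment event (cue onset, reward
    delivery, or each lick).  ``width`` is the full duration in seconds;
    Gaussian bumps use sigma = width / 4 so essentially all added rate
    falls inside ``center ± width/2``.
    """

    align: str  # 'cue' | 'reward' | 'lick'
    center: float
    width: float
    amplitude_hz: float
    trial_types: tuple[str, ...] = ("rewarded",)
    shape: str = "gaussian"  # 'gaussian' | 'boxcar'

    def anchor_times(self, trials: pd.DataFrame, licks: np.ndarray | None) -> np.ndarray:
        if self.align == "cue":
            sel = trials["trial_type"].isin(self.trial_types)
            t = trials.loc[sel, "cue_onset"].to_numpy(dtype=float)
        elif self.align == "reward":
            sel = trials["trial_type"].isin(self.trial_types)
            t = trials.loc[sel, "reward_time"].to_numpy(dtype=float)
        elif self.align == "lick":
            t = np.asarray([] if licks is None else licks, dtype=float)
        else:
            raise ConfigurationError(f"unknown alignment {self.align!r}")
        return t[~np.isnan(t)]

    def rate_at(self, t: np.ndarray, anchors: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t, dtype=float)
        if anchors.size == 0 or self.amplitude_hz == 0:
            return out
        for a in anchors:
            dt = t - (a + self.center)
            if self.shape == "gaussian":
                sigma = self.width / 4.0
                near = np.abs(dt) < 5 * sigma
                out[near] += self.amplitude_hz * np.exp(-0.5 * (dt[near] / sigma) ** 2)
            else:
                out[np.abs(dt) <= self.width / 2.0] += self.amplitude_hz
        return out


@dataclass
class RegimeProfile:
    """Baseline Cspk rate plus the regime's trial-locked bumps."""

    baseline_hz: float = 0.6
    bumps: list[Bump] = field(default_factory=list)
    nonresponsive_fraction: float = 0.25

    def rate_function(
        self, trials: pd.DataFrame, licks: np.ndarray | None, responsive: bool
    ):
        anchors = [b.anchor_times(trials, licks) for b in self.bumps]

        def rate(t: np.ndarray) -> np.ndarray:
            r = np.full_like(np.asarray(t, dtype=float), self.baseline_hz)
            if responsive:
                for b, a in zip(self.bumps, anchors):
                    r += b.rate_at(np.asarray(t, dtype=float), a)
            return r

        return rate

    @property
    def max_rate(self) -> float:
        return self.baseline_hz + sum(max(b.amplitude_hz, 0.0) for b in self.bumps)


def regime_profile(regime: str, baseline_hz: float = 0.6,
                   nonresponsive_fraction: float = 0.25) -> RegimeProfile:
    """Default trial-locked rate structure for each area/stage preset.

    Bump peak times follow the response latencies characteristic of each
    area: ~800 ms post-cue (200 ms post-reward) reward responses in naive
    lobule simplex, ~380 ms cue-locked responses after training, ~230 ms
    sensory responses in Crus I, ~300 ms in Crus II, plus a lick-locked
    component in naive Crus II.
    """
    RW, OM, UR = "rewarded", "omission", "unexpected_reward"
    B = Bump
    bumps: list[Bump]
    if regime == "LS_naive":
        bumps = [B("reward", 0.20, 0.20, 3.0, (RW, UR))]
    elif regime == "LS_trained":
        bumps = [
            B("cue", 0.38, 0.20, 3.0, (RW, OM)),
            B("reward", 0.20, 0.20, 3.0, (UR,)),
        ]
    elif regime == "CrusI_naive":
        bumps = [B("cue", 0.23, 0.20, 1.5, (RW, OM))]
    elif regime == "CrusI_trained":
        bumps = [
            B("cue", 0.23, 0.20, 3.0, (RW, OM)),
            B("reward", 0.20, 0.20, 2.5, (UR,)),
        ]
    elif regime == "CrusII_naive":
        bumps = [
            B("reward", 0.20, 0.20, 2.5, (RW, UR)),
            B("lick", 0.0, 0.15, 1.0, ()),
        ]
    elif regime == "CrusII_trained":
        bumps = [
            B("cue", 0.30, 0.20, 3.0, (RW, OM)),
            B("reward", 0.15, 0.20, 2.0, (RW, UR)),
        ]
    else:
        raise ConfigurationError(f"unknown regime {regime!r}")
    return RegimeProfile(baseline_hz, bumps, nonresponsive_fraction)


def generate_event_trains(
    trials: pd.DataFrame,
    regime: str | RegimeProfile,
    rng: np.random.Generator,
    duration: float,
    n_dendrites: int,
    licks: np.ndarray | None = None,
):
    """Draw per-dendrite inhomogeneous-Poisson Cspk event trains (seconds).

    Events are sampled by thinning a homogeneous Poisson process at the
    profile's maximum rate.  A ``nonresponsive_fraction`` of dendrites get
    baseline rate only.  Returns (list of sorted time arrays, responsive
    boolean array, profile).
    """
    profile = regime_profile(regime) if isinstance(regime, str) else regime
    responsive = rng.random(n_dendrites) >= profile.nonresponsive_fraction
    lam_max = profile.max_rate
    trains = []
    for d in range(n_dendrites):
        rate = profile.rate_function(trials, licks, bool(responsive[d]))
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        accept = rng.uniform(0.0, lam_max, size=n_cand) < rate(cand)
        trains.append(cand[accept])
    return trains, responsive, profile


# ---------------------------------------------------------------------------
# fluorescence rendering
# ---------------------------------------------------------------------------

DEFAULT_KERNEL = (0.05, 0.18)  # rise, decay time constants (s), GCaMP6f-like
DEFAULT_AMP_SIGMA = 0.35  # lognormal sigma of transient amplitudes


def kernel_peak_lag(rise: float, decay: float) -> float:
    """Analytic peak time of the difference-of-exponentials kernel."""
    if rise <= 0 or decay <= 0 or rise >= decay:
        raise ValueError("need 0 < rise < decay")
    return rise * decay / (decay - rise) * math.log(decay / rise)


def eval_kernel(t: np.ndarray, rise: float = 0.05, decay: float = 0.18) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak."""
    lag = kernel_peak_lag(rise, decay)
    norm = math.exp(-lag / decay) - math.exp(-lag / rise)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / decay) - np.exp(-t[pos] / rise)) / norm
    return out


def trace_noise_sd(snr: float, mask_area: float, amp_mean: float = 1.0) -> float:
    """Effective noise SD of a dendrite trace averaged over a mask.

    ``snr`` is the per-pixel transient-amplitude-to-noise ratio; averaging
    a K-pixel mask reduces the white pixel noise by sqrt(K).
    """
    return amp_mean / (snr * math.sqrt(mask_area))


def render_trace(
    event_times: np.ndarray,
    duration: float,
    frame_rate: float,
    rng: np.random.Generator | None = None,
    kernel: tuple[float, float] = DEFAULT_KERNEL,
    amp_mean: float = 1.0,
    amp_sigma: float = DEFAULT_AMP_SIGMA,
    noise_sd: float = 0.0,
    baseline: float = 1.0,
) -> np.ndarray:
    """Render a fluorescence trace: baseline + sum of transients + white noise.

    Amplitudes are lognormal with mean ``amp_mean`` (sigma in log units);
    the kernel is a difference of exponentials normalized to unit peak.
    """
    rise, decay = kernel
    if rise <= 0 or decay <= 0:
        raise ValueError("kernel time constants must be positive")
    n_frames = int(math.ceil(duration * frame_rate))
    trace = np.full(n_frames, baseline, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size:
        if rng is None and amp_sigma > 0:
            raise ValueError("rng required for stochastic amplitudes")
        if amp_sigma > 0:
            amps = amp_mean * np.exp(
                amp_sigma * rng.standard_normal(event_times.size) - amp_sigma**2 / 2
            )
        else:
            amps = np.full(event_times.size, amp_mean)
        support = int(math.ceil((8 * decay) * frame_rate))
        for t_e, a in zip(event_times, amps):
            k0 = int(math.floor(t_e * frame_rate))
            k1 = min(n_frames, k0 + support)
            if k1 <= 0 or k0 >= n_frames:
                continue
            k0 = max(k0, 0)
            tt = np.arange(k0, k1) / frame_rate - t_e
            trace[k0:k1] += a * eval_kernel(tt, rise, decay)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for noise")
        trace += noise_sd * rng.standard_normal(n_frames)
    return trace


# ---------------------------------------------------------------------------
# field of view and movie
# ---------------------------------------------------------------------------

def generate_fov(
    config: SessionConfig,
    rng: np.random.Generator,
    length: float = 40.0,
    width: float = 4.5,
    angle_jitter_deg: float = 10.0,
    margin: int = 2,
    max_retries: int = 2000,
) -> list[PixelMask]:
    """Place elongated (high-aspect) dendrite masks without overlap.

    Masks are rotated ellipses, elongated along the image columns as
    parasagittally-aligned Purkinje dendrites appear in these fields of
    view, with a small orientation jitter.  Raises :class:`PlacementError`
    when a non-overlapping placement cannot be found.
    """
    h, w = config.fov_shape
    occupied = np.zeros((h, w), dtype=bool)
    masks: list[PixelMask] = []
    half_l, half_w = length / 2.0, width / 2.0
    for d in range(config.n_dendrites):
        for attempt in range(max_retries):
            cy = rng.uniform(half_w + 1, h - half_w - 1)
            cx = rng.uniform(half_l + 1, w - half_l - 1)
            theta = math.radians(rng.uniform(-angle_jitter_deg, angle_jitter_deg))
            r0 = max(0, int(cy - half_l) - 1)
            r1 = min(h, int(cy + half_l) + 2)
            c0 = max(0, int(cx - half_l) - 1)
            c1 = min(w, int(cx + half_l) + 2)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dy, dx = yy - cy, xx - cx
            u = dx * math.cos(theta) + dy * math.sin(theta)  # along long axis
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            inside = (u / half_l) ** 2 + (v / half_w) ** 2 <= 1.0
            if not inside.any():
                continue
            dilated = ndimage.binary_dilation(inside, iterations=margin)
            if (occupied[r0:r1, c0:c1] & dilated).any():
                continue
            rows, cols = np.nonzero(inside)
            occupied[r0:r1, c0:c1] |= inside
            masks.append(
                PixelMask(rows=rows + r0, cols=cols + c0, id=d + 1, shape=(h, w))
            )
            break
        else:
            raise PlacementError(
                f"could not place dendrite {d + 1}/{config.n_dendrites} "
                f"in {config.fov_shape} after {max_retries} retries"
            )
    assert pairwise_disjoint(masks, (h, w))
    return masks


def render_movie(
    masks: list[PixelMask],
    traces: list[np.ndarray],
    shifts: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    background: float = 0.1,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render a movie: per-frame sum of mask-weighted traces + background,
    translated by per-frame (dy, dx) shifts (sub-pixel, linear
    interpolation), plus white pixel noise.  Returns float32 (T, H, W).
    """
    if len(masks) != len(traces):
        raise ValueError("one trace per mask required")
    lengths = {len(t) for t in traces}
    if len(lengths) > 1:
        raise ValueError("all traces must have equal length")
    n_frames = lengths.pop() if lengths else 0
    shape = shape or (masks[0].shape if masks else None)
    if shape is None:
        raise ValueError("image shape required")
    movie = np.full((n_frames, *shape), background, dtype=np.float32)
    for m, tr in zip(masks, traces):
        movie[:, m.rows, m.cols] += np.asarray(tr, dtype=np.float32)[:, None]
    if shifts is not None:
        shifts = np.asarray(shifts, dtype=float)
        if shifts.shape != (n_frames, 2):
            raise ValueError("shifts must be (n_frames, 2)")
        for t in range(n_frames):
            if shifts[t, 0] != 0 or shifts[t, 1] != 0:
                movie[t] = ndimage.shift(
                    movie[t], shifts[t], order=1, mode="constant", cval=background
                )
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for noise")
        for t in range(n_frames):  # framewise to bound memory
            movie[t] += noise_sd * rng.standard_normal(shape).astype(np.float32)
    return movie


# ---------------------------------------------------------------------------
# piezo movement sensor
# ---------------------------------------------------------------------------

@dataclass
class PiezoParams:
    """Breathing sinusoid plus randomly timed movement bursts."""

    rate: float = 200.0  # Hz
    breath_freq: float = 3.0
    breath_amp: float = 1.0
    burst_rate: float = 0.05  # Hz, spontaneous bursts
    burst_amp: float = 5.0
    burst_duration: float = 0.3
    burst_trials: tuple[int, ...] | None = None  # plant bursts pre-reward on these


@dataclass
class PiezoTrace:
    samples: np.ndarray
    rate: float

    def rms(self, start: float, stop: float) -> float:
        i0 = max(0, int(start * self.rate))
        i1 = min(len(self.samples), int(stop * self.rate))
        if i1 <= i0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples[i0:i1] ** 2)))


def generate_piezo(
    trials: pd.DataFrame,
    params: PiezoParams,
    rng: np.random.Generator,
    duration: float,
    reward_delay: float = 0.6,
) -> tuple[PiezoTrace, np.ndarray]:
    """Generate the movement-sensor trace; returns (trace, burst start times)."""
    n = int(math.ceil(duration * params.rate))
    t = np.arange(n) / params.rate
    samples = params.breath_amp * np.sin(2 * math.pi * params.breath_freq * t)

    bursts: list[float] = []
    if params.burst_rate > 0:
        n_b = rng.poisson(params.burst_rate * duration)
        bursts.extend(rng.uniform(0.0, duration, size=n_b))
    if params.burst_trials is not None and len(trials):
        slot = trial_slot_times(trials, reward_delay)
        for idx in params.burst_trials:
            # pre-reward window: between cue slot and reward delivery
            bursts.append(float(slot[idx]) + 0.1)

    n_env = int(params.burst_duration * params.rate)
    env = np.hanning(max(n_env, 3))
    for b in sorted(bursts):
        i0 = int(b * params.rate)
        i1 = min(n, i0 + len(env))
        if i0 >= n:
            continue
        samples[i0:i1] += (
            params.burst_amp * env[: i1 - i0] * rng.standard_normal(i1 - i0)
        )
    return PiezoTrace(samples=samples, rate=params.rate), np.sort(np.asarray(bursts))


# ---------------------------------------------------------------------------
# ground truth & full-session convenience
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Every planted quantity of one synthetic session."""

    masks: list[PixelMask] = field(default_factory=list)
    event_times: list[np.ndarray] = field(default_factory=list)
    responsive: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    profile: RegimeProfile | None = None
    kernel: tuple[float, float] = DEFAULT_KERNEL
    amp_sigma: float = DEFAULT_AMP_SIGMA
    planted_shifts: np.ndarray | None = None
    lick_params: LickParams | None = None
    piezo_bursts: np.ndarray | None = None
    fov_shape: tuple[int, int] | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "fov_shape": list(self.fov_shape) if self.fov_shape else None,
            "masks": [
                {"id": m.id, "rows": m.rows.tolist(), "cols": m.cols.tolist()}
                for m in self.masks
            ],
            "event_times": [et.tolist() for et in self.event_times],
            "responsive": np.asarray(self.responsive, dtype=bool).tolist(),
            "kernel": list(self.kernel),
            "amp_sigma": self.amp_sigma,
            "planted_shifts": (
                None if self.planted_shifts is None else self.planted_shifts.tolist()
            ),
            "lick_params": None if self.lick_params is None else asdict(self.lick_params),
            "piezo_bursts": (
                None if self.piezo_bursts is None else self.piezo_bursts.tolist()
            ),
            "profile": None
            if self.profile is None
            else {
                "baseline_hz": self.profile.baseline_hz,
                "nonresponsive_fraction": self.profile.nonresponsive_fraction,
                "bumps": [asdict(b) for b in self.profile.bumps],
            },
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        fov = tuple(d["fov_shape"]) if d.get("fov_shape") else None
        gt = cls(
            masks=[
                PixelMask(
                    rows=np.asarray(m["rows"]),
                    cols=np.asarray(m["cols"]),
                    id=m["id"],
                    shape=fov,
                )
                for m in d["masks"]
            ],
            event_times=[np.asarray(et, dtype=float) for et in d["event_times"]],
            responsive=np.asarray(d["responsive"], dtype=bool),
            kernel=tuple(d["kernel"]),
            amp_sigma=d["amp_sigma"],
            planted_shifts=(
                None
                if d["planted_shifts"] is None
                else np.asarray(d["planted_shifts"], dtype=float)
            ),
            lick_params=(
                None if d["lick_params"] is None else LickParams(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["lick_params"].items()
                })
            ),
            piezo_bursts=(
                None
                if d["piezo_bursts"] is None
                else np.asarray(d["piezo_bursts"], dtype=float)
            ),
            fov_shape=fov,
        )
        if d["profile"] is not None:
            p = d["profile"]
            gt.profile = RegimeProfile(
                baseline_hz=p["baseline_hz"],
                nonresponsive_fraction=p["nonresponsive_fraction"],
                bumps=[
                    Bump(**{
                        k: tuple(v) if k == "trial_types" else v
                        for k, v in b.items()
                    })
                    for b in p["bumps"]
                ],
            )
        return gt


@dataclass
class SessionData:
    """One fully generated synthetic session."""

    config: SessionConfig
    trials: pd.DataFrame
    licks: np.ndarray
    traces: list[np.ndarray]
    duration: float
    ground_truth: GroundTruth
    movie: np.ndarray | None = None
    piezo: PiezoTrace | None = None


def generate_session(
    config: SessionConfig,
    render: bool = False,
    motion_sd: float = 0.0,
    with_piezo: bool = False,
    piezo_params: PiezoParams | None = None,
    nonresponsive_fraction: float | None = None,
) -> SessionData:
    """Generate a complete session (behavior + events + traces [+ movie]).

    With ``render=True`` a noisy movie with optional rigid motion
    (per-frame Gaussian jitter of SD ``motion_sd`` pixels) is rendered;
    otherwise per-dendrite traces carry the mask-averaged noise level
    implied by ``config.snr`` directly.
    """
    rng = np.random.default_rng(config.seed)
    stage = "trained" if config.regime.endswith("trained") else "naive"

    trials = generate_trials(config, rng)
    duration = session_duration(trials, config)
    lick_params = LickParams.naive() if stage == "naive" else LickParams.trained()
    licks = generate_licks(
        trials, stage, lick_params, rng, duration, config.reward_delay_from_cue
    )

    profile = regime_profile(config.regime)
    if nonresponsive_fraction is not None:
        profile.nonresponsive_fraction = nonresponsive_fraction
    event_times, responsive, profile = generate_event_trains(
        trials, profile, rng, duration, config.n_dendrites, licks
    )

    masks = generate_fov(config, rng)
    mean_area = float(np.mean([m.area for m in masks])) if masks else 1.0

    pixel_noise_sd = 1.0 / config.snr
    gt = GroundTruth(
        masks=masks,
        event_times=event_times,
        responsive=responsive,
        profile=profile,
        lick_params=lick_params,
        fov_shape=config.fov_shape,
    )

    if render:
        traces = [
            render_trace(et, duration, config.frame_rate, rng, noise_sd=0.0)
            for et in event_times
        ]
        n_frames = len(traces[0]) if traces else 0
        shifts = None
        if motion_sd > 0:
            shifts = motion_sd * rng.standard_normal((n_frames, 2))
            gt.planted_shifts = shifts
        movie = render_movie(
            masks, traces, shifts=shifts, noise_sd=pixel_noise_sd, rng=rng
        )
    else:
        noise = trace_noise_sd(config.snr, mean_area)
        traces = [
            render_trace(et, duration, config.frame_rate, rng, noise_sd=noise)
            for et in event_times
        ]
        movie = None

    piezo = None
    if with_piezo:
        piezo, bursts = generate_piezo(
            trials, piezo_params or PiezoParams(), rng, duration,
            config.reward_delay_from_cue,
        )
        gt.piezo_bursts = bursts

    return SessionData(
        config=config,
        trials=trials,
        licks=licks,
        traces=traces,
        duration=duration,
        ground_truth=gt,
        movie=movie,
        piezo=piezo,
    )
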