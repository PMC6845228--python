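"""Session configuration for synthetic and real imaging sessions.

A :class:`SessionConfig` describes one classical-conditioning imaging session:
the trial structure (a 100 ms visual cue predicting reward 600 ms after cue
onset, separated by long 24-30 s inter-trial intervals, with a fraction of
special trials where the reward is omitted or delivered without the cue), the
imaging geometry (frame rate, field-of-view shape, number of Purkinje-cell
dendrites), and the regime preset naming the cerebellar area and training
stage whose complex-spike statistics the synthetic generator emulates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

REGIMES = (
    "LS_naive",
    "LS_trained",
    "CrusI_naive",
    "CrusI_trained",
    "CrusII_naive",
    "CrusII_trained",
)

SPECIAL_TRIAL_KINDS = ("omission", "unexpected_reward", "none")


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


@dataclass
class SessionConfig:
    """Parameters of one (synthetic) conditioning-plus-imaging session.

    Parameters
    ----------
    n_trials : int
        Number of trials in the session.
    iti_range : tuple of float
        Inter-trial interval bounds in seconds; ITIs are drawn uniformly.
    cue_duration : float
        Visual-cue duration, seconds.
    reward_delay_from_cue : float
        Delay from cue onset to reward delivery, seconds.
    special_trial_fraction : float
        Fraction of trials that are special (omission or unexpected reward).
    special_trial_kind : str
        One of ``omission``, ``unexpected_reward``, ``none``.
    frame_rate : float
        Imaging frame rate, Hz (30 for two-photon, 10 for mesoscale).
    fov_shape : tuple of int
        Field of view (rows, cols) in pixels.
    n_dendrites : int
        Number of Purkinje-cell dendrites planted in the field of view.
    regime : str
        Area/stage preset controlling trial-locked complex-spike rates.
    snr : float
        Transient amplitude divided by the per-pixel imaging noise SD.
        A trace averaged over a K-pixel dendrite mask therefore has an
        effective trace-level SNR of about ``snr * sqrt(K)``.
    seed : int
        Seed for all randomness derived from this config.
    """

    n_trials: int = 110
    iti_range: tuple[float, float] = (24.0, 30.0)
    cue_duration: float = 0.1
    reward_delay_from_cue: float = 0.6
    special_trial_fraction: float = 0.2
    special_trial_kind: str = "omission"
    frame_rate: float = 30.0
    fov_shape: tuple[int, int] = (264, 796)
    n_dendrites: int = 40
    regime: str = "LS_naive"
    snr: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_trials < 0:
            raise ConfigurationError("n_trials must be >= 0")
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid iti_range {self.iti_range!r}")
        if not 0.0 <= self.special_trial_fraction <= 1.0:
            raise ConfigurationError(
                f"special_trial_fraction {self.special_trial_fraction} not in [0, 1]"
            )
        if self.special_trial_kind not in SPECIAL_TRIAL_KINDS:
            raise ConfigurationError(
                f"unknown special_trial_kind {self.special_trial_kind!r}"
            )
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.reward_delay_from_cue <= 0:
            raise ConfigurationError("reward_delay_from_cue must be positive")
        if self.n_dendrites < 0:
            raise ConfigurationError("n_dendrites must be >= 0")
        if self.snr <= 0:
            raise ConfigurationError("snr must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iti_range"] = list(self.iti_range)
        d["fov_shape"] = list(self.fov_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "iti_range" in d:
            d["iti_range"] = tuple(d["iti_range"])
        if "fov_shape" in d:
            d["fov_shape"] = tuple(d["fov_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
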