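"""Rigid sub-pixel motion registration and dF/F normalization.

Registration uses frequency-domain phase correlation with upsampled local
refinement; frames are resampled with linear interpolation and edges filled
with the frame median.  dF/F is computed per trial against a short baseline
window before cue onset: (-0.9, -0.2] s at the 10 Hz mesoscale rate,
(-0.5, -0.1] s for 30 Hz two-photon data.  Mesoscale response latency is
the time of the peak first derivative within the 500 ms preceding the peak
of the trial-averaged dF/F.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

BASELINE_WINDOWS = {
    "mesoscale": (-0.9, -0.2),
    "two_photon": (-0.5, -0.1),
}


class DegenerateImageError(ValueError):
    """Zero-variance image; no shift can be estimated."""


class NormalizationError(ValueError):
    """Baseline fluorescence non-positive; dF/F undefined."""


def estimate_rigid_shift(
    image: np.ndarray, reference: np.ndarray, upsample: int = 20
) -> tuple[float, float]:
    """Sub-pixel (dy, dx) displacement of ``image`` relative to ``reference``.

    The returned shift is the translation that, applied to the reference,
    best reproduces the image (so a reference translated by (4, -3) yields
    (4, -3)).  Refinement resolution is 1/upsample pixel.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must share a shape")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(image) == 0 or np.ptp(reference) == 0:
        raise DegenerateImageError("flat image: shift undefined")
    shift, _, _ = phase_cross_correlation(
        reference, image, upsample_factor=upsample, normalization=None
    )
    # phase_cross_correlation returns the shift registering `image` onto the
    # reference, i.e. minus the displacement; flip to displacement.
    return (float(-shift[0]), float(-shift[1]))


def apply_shift(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Translate a frame (linear interpolation, median edge fill)."""
    return ndimage.shift(
        frame, shift, order=1, mode="constant", cval=float(np.median(frame))
    )


def register_movie(
    movie: np.ndarray, reference: np.ndarray, upsample: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Register every frame to the reference; returns (registered, shifts).

    ``shifts[t]`` is the estimated displacement of frame t; the frame is
    moved by its negation.  The shifts are returned for reuse (e.g. shifting
    segmentation masks when tracking dendrites across sessions).
    """
    if movie.ndim != 3 or movie.shape[1:] != reference.shape:
        raise ValueError("movie frames must match reference shape")
    shifts = np.zeros((movie.shape[0], 2))
    out = np.empty_like(movie)
    for t in range(movie.shape[0]):
        dy, dx = estimate_rigid_shift(movie[t], reference, upsample)
        shifts[t] = (dy, dx)
        if dy == 0 and dx == 0:
            out[t] = movie[t]
        else:
            out[t] = apply_shift(movie[t], (-dy, -dx))
    return out, shifts


@dataclass
class DffTrace:
    """Per-trial normalized fluorescence, times relative to the cue slot."""

    samples: np.ndarray
    times: np.ndarray  # s relative to trial's cue slot
    trial_index: int


def trial_dff(
    trace: np.ndarray,
    trials: pd.DataFrame,
    mode: str,
    frame_rate: float,
    trial_window: tuple[float, float] = (-1.0, 2.0),
    reward_delay: float = 0.6,
) -> list[DffTrace]:
    """Per-trial dF/F against the mode's pre-cue baseline window.

    F0 is the mean fluorescence over frames with time in
    (cue + b0, cue + b1], where (b0, b1) is the mode's baseline window;
    dF/F = (F - F0) / F0 over the trial window.  Trials extending past the
    trace are skipped.
    """
    if mode not in BASELINE_WINDOWS:
        raise ValueError(f"unknown mode {mode!r}")
    b0, b1 = BASELINE_WINDOWS[mode]
    trace = np.asarray(trace, dtype=float)
    t = np.arange(trace.size) / frame_rate
    from .synth import trial_slot_times

    out = []
    for i, slot in enumerate(trial_slot_times(trials, reward_delay)):
        base = (t > slot + b0) & (t <= slot + b1)
        win = (t > slot + trial_window[0]) & (t <= slot + trial_window[1])
        if not base.any() or not win.any():
            continue
        if slot + trial_window[1] > t[-1] + 0.5 / frame_rate:
            continue
        f0 = trace[base].mean()
        if f0 <= 0:
            raise NormalizationError(f"non-positive baseline F0={f0} on trial {i}")
        out.append(
            DffTrace(
                samples=(trace[win] - f0) / f0,
                times=t[win] - slot,
                trial_index=int(trials["trial"].iloc[i]) if "trial" in trials else i,
            )
        )
    return out


def mean_dff(dffs: list[DffTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Trial-average dF/F; trials must share the window (equal lengths)."""
    if not dffs:
        raise ValueError("no trials")
    n = min(d.samples.size for d in dffs)
    mat = np.stack([d.samples[:n] for d in dffs])
    return mat.mean(axis=0), dffs[0].times[:n]


def mesoscale_latency(
    samples: np.ndarray,
    times: np.ndarray,
    search_window: float = 0.5,
) -> float:
    """Response latency of a trial-averaged dF/F trace, relative to the cue.

    Finds the post-cue peak, then returns the time of the maximum one-frame
    forward difference within ``search_window`` seconds before that peak.
    The derivative between frames k and k+1 is assigned to frame k+1, so a
    step at time s yields latency s.  Invariant to additive offset and
    positive scaling.
    """
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float)
    post = times > 0
    if not post.any():
        raise ValueError("no post-cue samples")
    peak_idx = np.nonzero(post)[0][np.argmax(samples[post])]
    peak_t = times[peak_idx]
    d = np.diff(samples)
    d_times = times[1:]  # derivative assigned to the later frame
    in_win = (d_times > peak_t - search_window) & (d_times <= peak_t)
    if not in_win.any():
        return float(peak_t)
    k = np.nonzero(in_win)[0][np.argmax(d[in_win])]
    return float(d_times[k])
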