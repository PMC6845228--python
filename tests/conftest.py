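import numpy as np
import pytest

from cspk.config import SessionConfig
from cspk import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trials():
    """A 20-trial session with 20% omission trials (seeded)."""
    cfg = SessionConfig(n_trials=20, seed=7)
    return synth.generate_trials(cfg, np.random.default_rng(7)), cfg


@pytest.fixture(scope="session")
def rendered_scene():
    """A small rendered movie with planted masks and noiseless traces."""
    cfg = SessionConfig(
        n_trials=3, fov_shape=(64, 128), n_dendrites=4, seed=3, iti_range=(24, 30)
    )
    rng = np.random.default_rng(3)
    masks = synth.generate_fov(cfg, rng)
    duration, fr = 60.0, 30.0
    trials = synth.generate_trials(SessionConfig(n_trials=2, seed=3), rng)
    events, _, _ = synth.generate_event_trains(
        trials, "LS_naive", rng, duration, cfg.n_dendrites
    )
    traces = [synth.render_trace(e, duration, fr, rng) for e in events]
    movie = synth.render_movie(masks, traces, noise_sd=0.2, rng=rng)
    return {
        "config": cfg,
        "masks": masks,
        "events": events,
        "traces": traces,
        "movie": movie,
        "frame_rate": fr,
        "duration": duration,
    }
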