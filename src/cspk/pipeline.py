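"""End-to-end orchestration: synth -> register -> segment -> detect -> respond.

Each stage writes its interchange files into the run directory so that any
stage can be re-run or inspected in isolation; a :class:`RunManifest`
records the config snapshot, seeds, per-stage counts and SHA-256 digests
of every output file.  ``compare_learning`` contrasts a naive and a
trained session: the latency shift of the population response (the
post-reward peak of the naive session minus the pre-reward peak of the
trained one), per-category dendrite fractions, and population tests.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import summarize
from .config import SessionConfig
from .events import detect_events, event_raster, iti_frames
from .preprocess import register_movie
from .responses import (
    WindowSpec,
    baseline_peak_rates,
    build_psth,
    classify_event_responsive,
    classify_suppressed,
    peak_window_rates,
    population_response_test,
    psth_latency,
)
from .segment import extract_traces, filters_to_masks, pca_ica
from .synth import generate_session

logger = logging.getLogger(__name__)

STAGES = ("synth", "register", "segment", "detect", "respond")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: "RunManifest"):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    counts: dict[str, float] = field(default_factory=dict)
    timestamp: float = 0.0
    out_dir: str = ""

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def run_session(
    config: SessionConfig,
    out_dir: str | Path,
    motion_sd: float = 0.3,
    n_extra_components: int = 5,
    psth_window: tuple[float, float] = (-2.0, 2.0),
    record_timestamp: bool = False,
) -> RunManifest:
    """Run the full pipeline on one synthetic session; returns the manifest.

    ``record_timestamp=False`` keeps the manifest bit-reproducible for a
    fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        timestamp=time.time() if record_timestamp else 0.0,
        out_dir=str(out),
    )
    stage = "synth"
    try:
        sess = generate_session(config, render=True, motion_sd=motion_sd)
        cio.save_trials(out / "trials.csv", sess.trials)
        cio.save_licks(out / "licks.csv", sess.licks)
        sess.ground_truth.to_json(out / "ground_truth.json")
        manifest.counts["n_trials"] = len(sess.trials)
        manifest.counts["n_licks"] = int(sess.licks.size)
        manifest.stages.append(stage)

        stage = "register"
        reference = sess.movie.mean(axis=0)
        registered, shifts = register_movie(sess.movie, reference)
        cio.save_shifts(out / "shifts.csv", shifts)
        manifest.counts["shift_rms_px"] = float(np.sqrt((shifts**2).mean()))
        manifest.stages.append(stage)

        stage = "segment"
        filters = pca_ica(
            registered, config.n_dendrites + n_extra_components, seed=config.seed
        )
        masks = filters_to_masks(filters, registered)
        cio.save_masks(out / "masks.tif", masks, config.fov_shape)
        traces = extract_traces(registered, masks)
        cio.save_traces(out / "traces.h5", traces)
        manifest.counts["n_masks"] = len(masks)
        manifest.stages.append(stage)

        stage = "detect"
        n_frames = registered.shape[0]
        base = iti_frames(
            sess.trials, n_frames, config.frame_rate, config.reward_delay_from_cue
        )
        trains = [
            detect_events(tr, base, frame_rate=config.frame_rate, dendrite_id=m.id)
            for tr, m in zip(traces, masks)
        ]
        cio.save_events(out / "events.csv", trains, config.frame_rate)
        manifest.counts["n_events"] = int(sum(t.frames.size for t in trains))
        manifest.stages.append(stage)

        stage = "respond"
        _respond_stage(
            out, manifest, sess, trains, config, psth_window
        )
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        manifest.to_json(out / "manifest.json")
        raise PipelineError(stage, exc, manifest) from exc

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.record(p)
    manifest.to_json(out / "manifest.json")
    return manifest


def _respond_stage(out, manifest, sess, trains, config, psth_window):
    delay = config.reward_delay_from_cue
    rewarded = sess.trials[sess.trials["trial_type"] == "rewarded"]
    rasters = [
        event_raster(tr, rewarded, alignment="cue", window=psth_window)
        for tr in trains
    ]
    pop, rates = build_psth(rasters)
    cio.save_psth(out / "psth_rewarded.csv", pop)
    with_h5 = out / "rates_rewarded.h5"
    import h5py

    with h5py.File(with_h5, "w") as f:
        f.create_dataset("rates", data=rates)
        f.create_dataset("bin_centers", data=pop.bin_centers)

    special = sess.trials[sess.trials["trial_type"] != "rewarded"]
    if len(special) and not special["cue_onset"].isna().all():
        sp_rasters = [
            event_raster(tr, special, alignment="cue", window=psth_window)
            for tr in trains
        ]
        sp_pop, _ = build_psth(sp_rasters)
        cio.save_psth(out / "psth_special.csv", sp_pop)

    pre_w = WindowSpec.pre_reward(delay)
    post_w = WindowSpec.post_reward(delay)
    pre_rates, pre_peak = peak_window_rates(rates, pop, pre_w)
    post_rates, post_peak = peak_window_rates(rates, pop, post_w)
    base_rates, _ = baseline_peak_rates(rates, pop)
    test_pre = population_response_test(pre_rates, base_rates)
    test_post = population_response_test(post_rates, base_rates)

    resp_pre = classify_event_responsive(rates, pop.bin_centers, pre_w)
    resp_post = classify_event_responsive(rates, pop.bin_centers, post_w)
    supp_post = classify_suppressed(rates, pop.bin_centers, post_w)
    pd.DataFrame(
        {
            "dendrite_id": [t.dendrite_id for t in trains],
            "responsive_pre": resp_pre,
            "responsive_post": resp_post,
            "suppressed_post": supp_post,
            "peak_rate_pre": pre_rates,
            "peak_rate_post": post_rates,
        }
    ).to_csv(out / "classification.csv", index=False)

    beh = summarize(sess.trials, sess.licks)
    (out / "behavior.json").write_text(
        json.dumps(
            {
                "mean_reaction_time_s": beh.mean_reaction_time,
                "miss_rate": beh.miss_rate,
                "n_trials": beh.n_trials,
            }
        )
    )
    manifest.counts.update(
        {
            "pre_peak_time_s": pre_peak,
            "post_peak_time_s": post_peak,
            "p_pre": test_pre.p if not test_pre.degenerate else float("nan"),
            "p_post": test_post.p if not test_post.degenerate else float("nan"),
            "frac_responsive_pre": float(resp_pre.mean()),
            "frac_responsive_post": float(resp_post.mean()),
            "frac_suppressed_post": float(supp_post.mean()),
            "mean_reaction_time_s": beh.mean_reaction_time,
            "miss_rate": beh.miss_rate,
        }
    )


def _load_rates(out_dir: Path):
    import h5py

    with h5py.File(out_dir / "rates_rewarded.h5", "r") as f:
        return f["rates"][...], f["bin_centers"][...]


def compare_learning(
    manifest_naive: RunManifest,
    manifest_trained: RunManifest,
    naive_window: tuple[float, float] | None = None,
    trained_window: tuple[float, float] | None = None,
) -> dict:
    """Learning report: population-response latency shift and dendrite
    category fractions between a naive and a trained session.

    The shift is the naive session's post-reward PSTH peak time minus the
    trained session's pre-reward peak time (both cue-aligned).
    """
    cfg_n = SessionConfig.from_dict(manifest_naive.config)
    cfg_t = SessionConfig.from_dict(manifest_trained.config)
    if cfg_n.frame_rate != cfg_t.frame_rate or (
        cfg_n.reward_delay_from_cue != cfg_t.reward_delay_from_cue
    ):
        raise ValueError("sessions have mismatched frame rate or reward timing")
    delay = cfg_n.reward_delay_from_cue
    naive_window = naive_window or (delay, delay + 1.0)
    trained_window = trained_window or (0.0, delay)

    from .responses import Psth

    def pop_psth(man: RunManifest) -> tuple[Psth, np.ndarray]:
        rates, centers = _load_rates(Path(man.out_dir))
        n_d = rates.shape[0]
        sem = rates.std(axis=0, ddof=1) / np.sqrt(n_d) if n_d > 1 else 0 * centers
        return (
            Psth(
                bin_centers=centers,
                mean_rate=rates.mean(axis=0),
                sem=sem,
                n_trials=0,
                n_dendrites=n_d,
                frame_rate=cfg_n.frame_rate,
            ),
            rates,
        )

    pop_n, rates_n = pop_psth(manifest_naive)
    pop_t, rates_t = pop_psth(manifest_trained)
    lat_naive = psth_latency(pop_n, naive_window)
    lat_trained = psth_latency(pop_t, trained_window)

    pre_w = WindowSpec.pre_reward(delay)
    post_w = WindowSpec.post_reward(delay)
    resp_pre = classify_event_responsive(rates_t, pop_t.bin_centers, pre_w)
    resp_post = classify_event_responsive(rates_t, pop_t.bin_centers, post_w)
    fractions = {
        "pre_only": float((resp_pre & ~resp_post).mean()),
        "post_only": float((~resp_pre & resp_post).mean()),
        "both": float((resp_pre & resp_post).mean()),
        "neither": float((~resp_pre & ~resp_post).mean()),
    }

    def pop_test(pop, rates, window):
        r, _ = peak_window_rates(rates, pop, window)
        b, _ = baseline_peak_rates(rates, pop)
        t = population_response_test(r, b)
        return float("nan") if t.degenerate else t.p

    return {
        "latency_naive_s": lat_naive,
        "latency_trained_s": lat_trained,
        "latency_shift_s": lat_naive - lat_trained,
        "fractions_trained": fractions,
        "p_naive_post": pop_test(pop_n, rates_n, WindowSpec("naive_post", naive_window)),
        "p_trained_pre": pop_test(pop_t, rates_t, pre_w),
    }
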