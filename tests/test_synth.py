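"""Generator tests: trial structure, licks, event rates, rendering, piezo."""
import numpy as np
import pytest

from cspk import synth
from cspk.behavior import reaction_time
from cspk.config import ConfigurationError, SessionConfig


class TestGenerateTrials:
    def test_special_trial_count_exact(self, rng):
        cfg = SessionConfig(n_trials=100, special_trial_fraction=0.2)
        trials = synth.generate_trials(cfg, rng)
        assert (trials["trial_type"] == "omission").sum() == 20
        assert len(trials) == 100

    def test_empty_session(self, rng):
        trials = synth.generate_trials(SessionConfig(n_trials=0), rng)
        assert len(trials) == 0

    def test_cue_gaps_span_iti_range(self, rng):
        cfg = SessionConfig(n_trials=5, special_trial_fraction=0.0)
        trials = synth.generate_trials(cfg, rng)
        gaps = np.diff(trials["cue_onset"].to_numpy())
        span = cfg.reward_delay_from_cue + synth.POST_REWARD_S
        assert np.all(gaps >= 24.0 + span) and np.all(gaps <= 30.0 + span)

    def test_reward_follows_cue_by_fixed_delay(self, rng):
        trials = synth.generate_trials(SessionConfig(n_trials=50), rng)
        both = trials.dropna(subset=["cue_onset", "reward_time"])
        assert np.allclose(
            both["reward_time"] - both["cue_onset"], 0.6, atol=1e-12
        )

    def test_unexpected_reward_trials_lack_cue(self, rng):
        cfg = SessionConfig(
            n_trials=50, special_trial_kind="unexpected_reward"
        )
        trials = synth.generate_trials(cfg, rng)
        special = trials[trials["trial_type"] == "unexpected_reward"]
        assert len(special) == 10
        assert special["cue_onset"].isna().all()
        assert special["reward_time"].notna().all()

    def test_determinism(self):
        cfg = SessionConfig(n_trials=30, seed=11)
        a = synth.generate_trials(cfg, np.random.default_rng(11))
        b = synth.generate_trials(cfg, np.random.default_rng(11))
        assert a.equals(b)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(special_trial_fraction=1.5)


class TestGenerateLicks:
    def test_zero_miss_prob_gives_bout_every_trial(self, rng):
        trials = synth.generate_trials(
            SessionConfig(n_trials=20, special_trial_fraction=0), rng
        )
        params = synth.LickParams.trained()
        params.miss_prob = 0.0
        licks = synth.generate_licks(trials, "trained", params, rng)
        for cue in trials["cue_onset"]:
            after = licks[(licks > cue) & (licks <= cue + 2.0)]
            assert after.size >= 3
            # first three licks of the bout fall within 300 ms
            assert after[2] - after[0] <= 0.300

    @pytest.mark.parametrize("stage,rt_mean", [("naive", 0.74), ("trained", 0.54)])
    def test_reaction_time_recovered(self, stage, rt_mean):
        rng = np.random.default_rng(99)
        trials = synth.generate_trials(
            SessionConfig(n_trials=200, special_trial_fraction=0, seed=99), rng
        )
        params = synth.LickParams.naive() if stage == "naive" else synth.LickParams.trained()
        params.miss_prob = 0.0
        params.iti_lick_rate = 0.0
        licks = synth.generate_licks(trials, stage, params, rng)
        rts = [reaction_time(licks, c) for c in trials["cue_onset"]]
        rts = np.array([r for r in rts if r is not None])
        sem = params.rt_sd / np.sqrt(rts.size)
        assert abs(rts.mean() - rt_mean) < 3 * sem + 0.01  # small truncation bias

    def test_zero_iti_rate_no_licks_outside_trials(self, rng):
        trials = synth.generate_trials(SessionConfig(n_trials=10), rng)
        params = synth.LickParams.trained()
        params.iti_lick_rate = 0.0
        licks = synth.generate_licks(trials, "trained", params, rng)
        slots = synth.trial_slot_times(trials, 0.6)
        in_trial = np.zeros(licks.size, dtype=bool)
        for s in slots:
            in_trial |= (licks >= s) & (licks <= s + 0.6 + 2.5)
        assert in_trial.all()

    def test_unknown_stage_rejected(self, rng, small_trials):
        with pytest.raises(ConfigurationError):
            synth.generate_licks(small_trials[0], "expert", rng=rng)


class TestEventTrains:
    def test_homogeneous_when_bumps_zero(self, rng):
        trials = synth.generate_trials(SessionConfig(n_trials=5), rng)
        profile = synth.RegimeProfile(baseline_hz=0.6, bumps=[], nonresponsive_fraction=0)
        duration = 2000.0
        trains, resp, _ = synth.generate_event_trains(trials, profile, rng, duration, 5)
        for t in trains:
            rate = t.size / duration
            sem = np.sqrt(0.6 / duration)
            assert abs(rate - 0.6) < 3 * sem

    def test_planted_bump_height_by_direct_counting(self):
        rng = np.random.default_rng(5)
        cfg = SessionConfig(n_trials=100, special_trial_fraction=0, seed=5)
        trials = synth.generate_trials(cfg, rng)
        bump = synth.Bump("cue", 0.3, 0.2, 3.0, ("rewarded",), shape="boxcar")
        profile = synth.RegimeProfile(0.6, [bump], nonresponsive_fraction=0)
        duration = synth.session_duration(trials, cfg)
        trains, _, _ = synth.generate_event_trains(trials, profile, rng, duration, 20)
        counts = []
        for t in trains:
            for cue in trials["cue_onset"]:
                counts.append(
                    np.count_nonzero((t >= cue + 0.2) & (t <= cue + 0.4))
                )
        counts = np.asarray(counts, dtype=float)
        expected = (0.6 + 3.0) * 0.2  # integrated rate in the bump window
        sem = np.sqrt(expected / counts.size)
        assert abs(counts.mean() - expected) < 3 * sem

    def test_ls_naive_omission_has_no_post_reward_elevation(self):
        rng = np.random.default_rng(6)
        cfg = SessionConfig(n_trials=200, special_trial_fraction=0.5, seed=6)
        trials = synth.generate_trials(cfg, rng)
        duration = synth.session_duration(trials, cfg)
        profile = synth.regime_profile("LS_naive", nonresponsive_fraction=0.0)
        trains, _, _ = synth.generate_event_trains(trials, profile, rng, duration, 20)
        om = trials[trials["trial_type"] == "omission"]
        counts = []
        for t in trains:
            for slot in om["cue_onset"]:
                counts.append(np.count_nonzero((t >= slot + 0.6) & (t <= slot + 1.2)))
        counts = np.asarray(counts, dtype=float)
        expected = 0.6 * 0.6  # baseline only
        sem = np.sqrt(expected / counts.size)
        assert abs(counts.mean() - expected) < 3 * sem

    def test_unknown_regime_rejected(self, rng, small_trials):
        with pytest.raises(ConfigurationError):
            synth.generate_event_trains(small_trials[0], "LS_expert", rng, 100.0, 2)


class TestRenderTrace:
    def test_no_events_no_noise_constant(self):
        trace = synth.render_trace(np.array([]), 10.0, 30.0, baseline=2.0)
        assert np.allclose(trace, 2.0)

    def test_single_event_peaks_at_kernel_lag(self):
        fr = 1000.0  # fine sampling isolates the analytic peak
        t_event = 1.0
        trace = synth.render_trace(
            np.array([t_event]), 3.0, fr, amp_sigma=0.0, noise_sd=0.0
        )
        lag = synth.kernel_peak_lag(0.05, 0.18)
        peak_time = np.argmax(trace) / fr
        assert abs(peak_time - (t_event + lag)) < 2.0 / fr
        assert abs(trace.max() - 2.0) < 1e-3  # baseline 1 + unit amplitude

    def test_superposition(self):
        a = synth.render_trace(np.array([1.0]), 10.0, 30.0, amp_sigma=0.0, baseline=0.0)
        b = synth.render_trace(np.array([3.0]), 10.0, 30.0, amp_sigma=0.0, baseline=0.0)
        ab = synth.render_trace(
            np.array([1.0, 3.0]), 10.0, 30.0, amp_sigma=0.0, baseline=0.0
        )
        assert np.allclose(ab, a + b, atol=1e-12)

    def test_nonpositive_kernel_rejected(self):
        with pytest.raises(ValueError):
            synth.render_trace(np.array([1.0]), 5.0, 30.0, kernel=(0.0, 0.18))


class TestFov:
    def test_masks_disjoint_and_in_bounds(self, rendered_scene):
        masks = rendered_scene["masks"]
        shape = rendered_scene["config"].fov_shape
        from cspk.masks import pairwise_disjoint

        assert pairwise_disjoint(masks, shape)
        for m in masks:
            assert m.rows.min() >= 0 and m.rows.max() < shape[0]
            assert m.cols.min() >= 0 and m.cols.max() < shape[1]

    def test_single_mask(self, rng):
        cfg = SessionConfig(fov_shape=(50, 100), n_dendrites=1)
        masks = synth.generate_fov(cfg, rng)
        assert len(masks) == 1

    def test_elongation_by_image_moments(self, rng):
        cfg = SessionConfig(fov_shape=(120, 300), n_dendrites=10)
        masks = synth.generate_fov(cfg, rng, length=45.0, width=4.5)
        for m in masks:
            assert m.aspect_ratio() >= 5.0

    def test_placement_failure_raises(self, rng):
        cfg = SessionConfig(fov_shape=(20, 50), n_dendrites=30)
        with pytest.raises(synth.PlacementError):
            synth.generate_fov(cfg, rng, max_retries=50)


class TestRenderMovie:
    def test_identity_motion_mean_image(self, rng):
        cfg = SessionConfig(fov_shape=(40, 60), n_dendrites=2)
        masks = synth.generate_fov(cfg, rng, length=15, width=3)
        traces = [np.ones(10) * 2.0, np.ones(10) * 3.0]
        movie = synth.render_movie(masks, traces, background=0.5)
        expected = np.full((40, 60), 0.5)
        expected[masks[0].rows, masks[0].cols] += 2.0
        expected[masks[1].rows, masks[1].cols] += 3.0
        assert np.allclose(movie.mean(axis=0), expected, atol=1e-6)

    def test_integer_shift_is_exact_translation(self, rng):
        cfg = SessionConfig(fov_shape=(40, 60), n_dendrites=2)
        masks = synth.generate_fov(cfg, rng, length=15, width=3)
        traces = [np.ones(2), np.ones(2)]
        shifts = np.array([[0.0, 0.0], [3.0, -2.0]])
        movie = synth.render_movie(masks, traces, shifts=shifts, background=0.0)
        moved = np.zeros_like(movie[0])
        moved[3:, :-2] = movie[0][:-3, 2:]
        assert np.allclose(movie[1], moved, atol=1e-6)

    def test_subpixel_shift_preserves_mass(self, rng):
        cfg = SessionConfig(fov_shape=(40, 60), n_dendrites=1)
        masks = synth.generate_fov(cfg, rng, length=15, width=3)
        traces = [np.ones(2)]
        shifts = np.array([[0.0, 0.0], [0.5, 0.0]])
        movie = synth.render_movie(masks, traces, shifts=shifts, background=0.0)
        assert movie[1].sum() == pytest.approx(movie[0].sum(), rel=1e-6)

    def test_length_mismatch_rejected(self, rng):
        cfg = SessionConfig(fov_shape=(40, 60), n_dendrites=2)
        masks = synth.generate_fov(cfg, rng, length=15, width=3)
        with pytest.raises(ValueError):
            synth.render_movie(masks, [np.ones(5), np.ones(6)])


class TestPiezo:
    def test_pure_breathing_spectral_peak(self, rng, small_trials):
        trials, _ = small_trials
        params = synth.PiezoParams(burst_rate=0.0, breath_freq=3.0)
        trace, bursts = synth.generate_piezo(trials, params, rng, duration=60.0)
        assert bursts.size == 0
        spectrum = np.abs(np.fft.rfft(trace.samples))
        freqs = np.fft.rfftfreq(trace.samples.size, 1.0 / trace.rate)
        assert abs(freqs[np.argmax(spectrum[1:]) + 1] - 3.0) < 0.1

    def test_planted_bursts_rank_top_decile(self, rng):
        cfg = SessionConfig(n_trials=20, special_trial_fraction=0, seed=21)
        trials = synth.generate_trials(cfg, np.random.default_rng(21))
        planted = (3, 11)
        params = synth.PiezoParams(burst_rate=0.0, burst_trials=planted)
        duration = synth.session_duration(trials, cfg)
        trace, _ = synth.generate_piezo(trials, params, rng, duration)
        slots = synth.trial_slot_times(trials, 0.6)
        rms = np.array([trace.rms(s, s + 0.6) for s in slots])
        top2 = set(np.argsort(rms)[-2:].tolist())
        assert top2 == set(planted)

    def test_zero_amplitude_all_zero(self, rng, small_trials):
        params = synth.PiezoParams(breath_amp=0.0, burst_rate=0.0)
        trace, _ = synth.generate_piezo(small_trials[0], params, rng, duration=30.0)
        assert np.allclose(trace.samples, 0.0)


class TestGroundTruth:
    def test_json_roundtrip(self, tmp_path, rendered_scene):
        gt = synth.GroundTruth(
            masks=rendered_scene["masks"],
            event_times=rendered_scene["events"],
            responsive=np.array([True, False, True, True]),
            profile=synth.regime_profile("LS_trained"),
            planted_shifts=np.array([[0.5, -0.25], [0.0, 1.0]]),
            lick_params=synth.LickParams.naive(),
            piezo_bursts=np.array([1.5, 20.0]),
            fov_shape=rendered_scene["config"].fov_shape,
        )
        path = tmp_path / "gt.json"
        gt.to_json(path)
        back = synth.GroundTruth.from_json(path)
        assert len(back.masks) == len(gt.masks)
        for a, b in zip(back.masks, gt.masks):
            assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)
        for a, b in zip(back.event_times, gt.event_times):
            assert np.allclose(a, b)
        assert np.array_equal(back.responsive, gt.responsive)
        assert back.profile.baseline_hz == gt.profile.baseline_hz
        assert back.profile.bumps[0].trial_types == gt.profile.bumps[0].trial_types
        assert np.allclose(back.planted_shifts, gt.planted_shifts)
        assert back.lick_params == gt.lick_params

    def test_session_determinism(self):
        cfg = SessionConfig(
            n_trials=5, fov_shape=(48, 96), n_dendrites=3, seed=42
        )
        a = synth.generate_session(cfg)
        b = synth.generate_session(cfg)
        assert a.trials.equals(b.trials)
        assert np.array_equal(a.licks, b.licks)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta, tb)
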