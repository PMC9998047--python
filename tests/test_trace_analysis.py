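import numpy as np
import pytest

from omrkit.controller import canonical_profile
from omrkit.simulator import Condition
from omrkit.synthetic_data import SynthSpec, generate_session, render_bout_train
from omrkit.trace_analysis import (
    AnalysisConfig,
    PositionTrace,
    bout_measures,
    bout_rate,
    direction_change_times,
    ema,
    extract_bouts,
    extract_omr_trajectories,
    instantaneous_speed,
    mean_swim_speed,
    omr_ratio,
    quartile_profiles,
    relative_speed_profile,
    resample_trace,
)

from conftest import trace_from_frame


def make_trace(x, direction=1, stimulus_speed=8.0, dt=0.01, **kw):
    x = np.asarray(x, dtype=float)
    return PositionTrace(
        t=np.arange(len(x)) * dt,
        x=x,
        direction=direction,
        stimulus_speed=stimulus_speed,
        **kw,
    )


def bout_train_trace(onset_steps, mags, n_steps, direction=1, x0=10.0, noise=None):
    """Noiseless (or lightly noisy) position trace from a known bout train."""
    profile = canonical_profile()
    v = render_bout_train(onset_steps, mags, n_steps, profile)
    xs = x0 + np.concatenate([[0.0], np.cumsum(v[:-1]) * 0.01])
    if noise is not None:
        xs = xs + noise
    x = xs if direction == 1 else 300.0 - xs
    return make_trace(x, direction=direction)


class TestResample:
    def test_short_gap_filled(self, config):
        t = np.concatenate([np.arange(0, 0.5, 0.01), np.arange(0.61, 1.0, 0.01)])
        x = t * 10.0
        trace = resample_trace(t, x, config, direction=1, stimulus_speed=8.0)
        assert not np.any(np.isnan(trace.x))
        np.testing.assert_allclose(trace.x, trace.t * 10.0, atol=1e-9)

    def test_long_gap_marked_missing(self, config):
        t = np.concatenate([np.arange(0, 0.5, 0.01), np.arange(0.70, 1.0, 0.01)])
        x = t * 10.0
        trace = resample_trace(t, x, config, direction=1, stimulus_speed=8.0)
        gap = (trace.t > 0.49 + 1e-9) & (trace.t < 0.70 - 1e-9)
        assert np.all(np.isnan(trace.x[gap]))
        assert not np.any(np.isnan(trace.x[~gap]))

    def test_uniform_input_unchanged(self, config):
        t = np.arange(0, 2, 0.01)
        x = np.sin(t)
        trace = resample_trace(t, x, config, direction=1, stimulus_speed=8.0)
        np.testing.assert_allclose(trace.x, x, atol=1e-12)

    def test_empty_input_rejected(self, config):
        with pytest.raises(ValueError):
            resample_trace([], [], config, direction=1, stimulus_speed=8.0)


class TestEMA:
    def test_constant_sequence(self):
        np.testing.assert_allclose(ema(np.full(50, 3.3), 0.05), 3.3)

    def test_alpha_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_allclose(ema(x, 1.0), x)

    def test_printed_finite_history_formula(self):
        # adjusted weights: y1 = (x1 + 0.95 x0) / (1 + 0.95)
        y = ema([0.0, 1.0], 0.05)
        assert y[1] == pytest.approx(1.0 / 1.95)

    def test_matches_direct_weight_evaluation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        alpha = 0.1
        y = ema(x, alpha)
        for t in (0, 5, 29):
            w = (1 - alpha) ** np.arange(t + 1)
            assert y[t] == pytest.approx(np.dot(w, x[t::-1]) / w.sum())


class TestDirectionChanges:
    def test_monotone_trace_has_no_crossings(self, config):
        trace = make_trace(np.linspace(0, 100, 1000))
        assert len(direction_change_times(trace, config)) == 0

    def test_reversal_yields_single_lagged_crossing(self, config):
        """A forward-then-backward trace gives exactly one crossing, after
        the true reversal by no more than the slow EMA's ~5 s memory."""
        fwd = np.linspace(0, 50, 1000)
        back = 50 - np.linspace(0, 50, 1000)[1:]
        trace = make_trace(np.concatenate([fwd, back]))
        times = direction_change_times(trace, config)
        assert len(times) == 1
        assert 10.0 < times[0] < 15.0

    def test_time_reversal_symmetry(self, config):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0.05, 0.2, 2000))
        trace = make_trace(x)
        flipped = make_trace(x[::-1])
        fwd_on_flipped = direction_change_times(flipped, config)
        rev = direction_change_times(trace, config, reverse_time=True)
        # reversing the trace and reversing time visit the same crossings
        np.testing.assert_allclose(
            sorted(trace.t[-1] - rev), sorted(fwd_on_flipped), atol=0.02
        )


class TestTrajectories:
    def test_stationary_fish_yields_nothing(self, config):
        rng = np.random.default_rng(0)
        trace = make_trace(100 + rng.normal(0, 0.05, 3000))
        assert extract_omr_trajectories(trace, config) == []

    def test_omr_only_session_covered_by_one_trajectory(self, config):
        rng = np.random.default_rng(4)
        onsets = np.arange(50, 5900, 80)
        trace = bout_train_trace(
            onsets, np.full(len(onsets), 5.0), 6000,
            noise=rng.normal(0, 0.05, 6000),
        )
        trajectories = extract_omr_trajectories(trace, config)
        margin = trace.end_margin_index(config.end_margin)
        pre_margin_time = trace.t[min(margin, len(trace.t) - 1)]
        covered = sum(tr.duration for tr in trajectories)
        assert covered >= 0.9 * pre_margin_time

    def test_swimming_against_stimulus_excluded(self, config):
        trace = make_trace(np.linspace(250, 50, 3000))  # steady negative motion
        assert extract_omr_trajectories(trace, config) == []

    def test_missing_data_splits_segments(self, config):
        x = np.linspace(10, 100, 4000)
        x[2000:2100] = np.nan
        trace = make_trace(x)
        trajectories = extract_omr_trajectories(trace, config)
        assert len(trajectories) == 2
        for tr in trajectories:
            assert not np.any(np.isnan(trace.x[tr.start_index : tr.end_index]))

    def test_backward_traverse_shares_code_path(self, config):
        rng = np.random.default_rng(5)
        onsets = np.arange(50, 5900, 80)
        fwd = bout_train_trace(
            onsets, np.full(len(onsets), 5.0), 6000,
            noise=rng.normal(0, 0.05, 6000),
        )
        back = make_trace(300.0 - fwd.x, direction=-1)
        a = extract_omr_trajectories(fwd, config)
        b = extract_omr_trajectories(back, config)
        assert len(a) == len(b)
        assert a[0].displacement == pytest.approx(b[0].displacement)


class TestSpeedSummaries:
    def test_ratio_of_equal_speeds_is_one(self):
        assert omr_ratio(8.0, 8.0) == 1.0

    def test_ground_truth_displacement_recovered(self, config):
        trace = make_trace(np.linspace(20, 140, 3001))  # 120 mm in 30 s
        trajs = extract_omr_trajectories(trace, config)
        assert mean_swim_speed(trajs) == pytest.approx(4.0, rel=0.01)

    def test_no_trajectories_raises(self):
        with pytest.raises(ValueError):
            mean_swim_speed([])


class TestBoutExtraction:
    def test_flat_noise_has_no_bouts(self, config):
        rng = np.random.default_rng(6)
        trace = make_trace(150 + rng.normal(0, 0.05, 3000))
        assert extract_bouts(trace, config) == []

    def test_known_onsets_recovered(self, config):
        rng = np.random.default_rng(7)
        true_onsets = np.arange(100, 2900, 140)
        trace = bout_train_trace(
            true_onsets, np.full(len(true_onsets), 8.0), 3000,
            noise=rng.normal(0, 0.05, 3000),
        )
        bouts = extract_bouts(trace, config)
        detected = np.array([b.onset_index for b in bouts])
        matched = sum(
            np.any(np.abs(detected - t0) <= 3) for t0 in true_onsets
        )
        assert matched >= len(true_onsets) - 1

    def test_close_pair_both_detected(self, config):
        trace = bout_train_trace([500, 530], [8.0, 8.0], 1500)
        bouts = extract_bouts(trace, config)
        detected = np.array([b.onset_index for b in bouts])
        assert np.any(np.abs(detected - 500) <= 3)
        assert np.any(np.abs(detected - 530) <= 3)


class TestBoutMeasures:
    def test_constant_speed_initial(self, config):
        # 10 mm/s for 100 ms then rest
        x = np.concatenate([np.linspace(0, 1.0, 11), np.full(200, 1.0)])
        trace = make_trace(x)
        (event,) = bout_measures(trace, [0], config)
        assert event.initial_speed == pytest.approx(10.0)

    def test_weak_bout_flagged_degenerate(self, config):
        x = np.concatenate([np.linspace(0, 0.3, 100), np.full(100, 0.3)])
        trace = make_trace(x)  # never exceeds 5 mm/s
        (event,) = bout_measures(trace, [0], config)
        assert event.degenerate
        assert event.active_duration == 0.0

    def test_scaling_doubles_speeds_and_extends_duration(self, config):
        weak = bout_train_trace([100], [4.0], 400)
        strong = bout_train_trace([100], [8.0], 400)
        (b_weak,) = bout_measures(weak, [100], config)
        (b_strong,) = bout_measures(strong, [100], config)
        assert b_strong.initial_speed == pytest.approx(2 * b_weak.initial_speed)
        assert b_strong.peak_speed == pytest.approx(2 * b_weak.peak_speed, rel=1e-6)
        assert b_strong.active_duration > b_weak.active_duration

    def test_intensity_measures_rank_bouts_identically(self, config):
        """Initial speed, peak speed and displacement assign the same
        quartile to at least 90% of completed noiseless fixed-profile bouts."""
        rng = np.random.default_rng(8)
        cond = Condition(height=32, stimulus_speed=8)
        spec = SynthSpec(
            conditions=(cond,), n_fish=1, seed=21, noise_sd=0.0, drop_probability=0.0
        )
        measures = []
        for fish in range(4):
            frame, truths = generate_session(spec, cond, seed=fish)
            for trav in (0, 1):
                df = frame[frame["traverse_id"] == trav]
                trace = trace_from_frame(df, config, 8.0)
                onsets = (truths[trav].onset_times / 0.01).round().astype(int)
                events = bout_measures(trace, onsets, config)
                # completed bouts only: the next onset falls beyond the
                # profile support, so displacement is not truncated
                measures += [
                    b
                    for b in events
                    if not b.partial
                    and (np.isnan(b.interval_to_next) or b.interval_to_next >= 1.0)
                ]
        assert len(measures) >= 40

        def quartile(values):
            values = np.asarray(values)
            edges = np.quantile(values, [0.25, 0.5, 0.75])
            return np.searchsorted(edges, values, side="right")

        q_init = quartile([b.initial_speed for b in measures])
        q_peak = quartile([b.peak_speed for b in measures])
        q_disp = quartile([b.displacement for b in measures])
        assert np.mean(q_init == q_peak) >= 0.9
        assert np.mean(q_init == q_disp) >= 0.9


class TestProfiles:
    def test_profile_has_unit_mean_for_any_selection(self, config):
        rng = np.random.default_rng(9)
        onsets = list(range(100, 2700, 130))
        trace = bout_train_trace(
            onsets, rng.uniform(4, 16, len(onsets)), 3000,
            noise=rng.normal(0, 0.05, 3000),
        )
        for subset in (onsets, onsets[::2], onsets[:5]):
            prof = relative_speed_profile(
                [trace], [subset], config, all_onsets_per_trace=[onsets]
            )
            assert prof.mean() == pytest.approx(1.0, abs=1e-12)

    def test_quartile_profiles_share_shape(self, config):
        rng = np.random.default_rng(10)
        traces, bouts, onsets_all = [], [], []
        for _ in range(4):
            onsets = list(range(100, 5700, 110))
            trace = bout_train_trace(
                onsets, rng.uniform(4, 16, len(onsets)), 6000,
                noise=rng.normal(0, 0.05, 6000),
            )
            traces.append(trace)
            bouts.append(extract_bouts(trace, config))
            onsets_all.append([b.onset_index for b in bouts[-1]])
        overall = relative_speed_profile(traces, onsets_all, config)
        for q in quartile_profiles(traces, bouts, config):
            assert np.max(np.abs(q - overall)) < 0.1 * overall.max()


class TestBoutRate:
    def test_rate_from_counts(self, config):
        rng = np.random.default_rng(11)
        onsets = np.arange(100, 2900, 140)
        trace = bout_train_trace(
            onsets, np.full(len(onsets), 8.0), 3000,
            noise=rng.normal(0, 0.05, 3000),
        )
        trajs = extract_omr_trajectories(trace, config)
        bouts = extract_bouts(trace, config)
        rate = bout_rate(bouts, trajs)
        total = sum(tr.duration for tr in trajs)
        inside = sum(
            1
            for b in bouts
            if any(tr.contains_time(b.onset_time) for tr in trajs)
        )
        assert rate == pytest.approx(inside / total)
        assert rate == pytest.approx(1 / 1.4, rel=0.15)

    def test_no_bouts_zero_rate(self, config):
        trace = make_trace(np.linspace(10, 100, 2000))
        trajs = extract_omr_trajectories(trace, config)
        assert bout_rate([], trajs) == 0.0

    def test_empty_trajectories_raise(self):
        with pytest.raises(ValueError):
            bout_rate([], [])


def test_traverse_averaging_is_order_invariant(config):
    """Session speed weights the two traverses equally; 2 and 4 mm/s
    traverses give 3 mm/s whatever their durations or order."""
    from omrkit.trace_analysis import _session_summary

    slow = make_trace(10 + 2.0 * np.arange(4000) * 0.01)  # 2 mm/s for 40 s
    fast = make_trace(10 + 4.0 * np.arange(1500) * 0.01)  # 4 mm/s for 15 s
    for order in ([slow, fast], [fast, slow]):
        summary = _session_summary(order, config)
        assert summary["swim_speed_mm_s"] == pytest.approx(3.0, rel=0.01)
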