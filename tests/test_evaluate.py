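"""Evaluation pipeline: segmentation, filtering, resampling, DTW, metrics."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_normalized_dtw
from rowsim._dtw import local_cost_matrix, normalized_dtw
from rowsim.evaluate import (
    Cycle,
    MetricConfig,
    dtw_dissimilarity,
    evaluate_run,
    filter_cycles,
    reference_cycle,
    resample_cycle,
    segment_cycles,
    spatial_error,
    spatial_variability,
    velocity_error,
    velocity_variability,
)
from rowsim.reference import ReferenceSpec, Trajectory, generate_reference
from rowsim.synthrower import RowerProfile, simulate_run


def make_cycle(duration=2.5, n=250, theta=None, delta=None, index=0, t0=0.0):
    t = t0 + np.linspace(0.0, duration * (n - 1) / n, n)
    return Cycle(times=t,
                 theta=np.zeros(n) if theta is None else np.asarray(theta, float),
                 delta=np.zeros(n) if delta is None else np.asarray(delta, float),
                 duration=duration, index_in_run=index)


class TestSegmentation:
    def test_reference_run_yields_48_cycles(self, ref_traj_120, config):
        assert len(segment_cycles(ref_traj_120, config)) == 48

    def test_short_trajectory_yields_nothing(self, spec, config):
        traj = generate_reference(spec, duration=2.0, sample_rate=100.0)
        with pytest.warns(RuntimeWarning):
            assert segment_cycles(traj, config) == []

    def test_boundaries_match_generator_ground_truth(self, config):
        # Modest smooth noise plus cadence jitter; detected catches must
        # land within one sample (0.01 s) of the injected cycle starts.
        for seed in range(5):
            run = simulate_run(RowerProfile(spatial_bias_deg=0.0,
                                            spatial_noise_deg=0.05,
                                            cadence_jitter_sd=0.05, seed=seed),
                               duration=60.0)
            detected = [c.times[0] for c in segment_cycles(run.trajectory, config)]
            for t in detected:
                assert np.min(np.abs(run.boundary_times - t)) <= 0.01 + 1e-12

    def test_cycles_tile_the_run_contiguously(self, ref_traj_120, config):
        cycles = segment_cycles(ref_traj_120, config)
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert b.times[0] == pytest.approx(a.times[0] + a.duration)
        assert sum(c.duration for c in cycles) == pytest.approx(
            ref_traj_120.duration)


class TestFilter:
    def test_head_and_tail_exclusions(self, ref_traj_120, config):
        cycles = segment_cycles(ref_traj_120, config)
        assert len(filter_cycles(cycles, config)) == 48 - 3 - 1

    def test_out_of_band_cycle_removed(self, config):
        cycles = [make_cycle(duration=2.5, index=i) for i in range(10)]
        slow = replace(cycles[5], duration=3.0)  # 20 strokes/min
        cycles[5] = slow
        valid = filter_cycles(cycles, config)
        assert len(valid) == 10 - 3 - 1 - 1
        assert all(22.0 <= c.cadence_spm <= 26.0 for c in valid)

    def test_band_edges_inclusive(self):
        # Band endpoints chosen exactly representable: 60/3 = 20, 60/2 = 30.
        cfg = MetricConfig(cadence_band_spm=(20.0, 30.0))
        cycles = ([make_cycle(index=i) for i in range(3)]
                  + [make_cycle(duration=3.0, index=3),
                     make_cycle(duration=2.0, index=4)]
                  + [make_cycle(index=5)])
        assert len(filter_cycles(cycles, cfg)) == 2

    def test_all_out_of_band_warns_and_empties(self, config):
        cycles = [make_cycle(duration=3.0, index=i) for i in range(8)]
        with pytest.warns(RuntimeWarning):
            assert filter_cycles(cycles, config) == []


class TestResample:
    def test_resamples_to_250_points(self, config):
        cyc = make_cycle(n=237, theta=np.random.default_rng(0).random(237))
        assert len(resample_cycle(cyc, config.resample_points)) == 250

    def test_constant_cycle_stays_constant(self):
        cyc = make_cycle(theta=np.full(250, 4.0))
        out = resample_cycle(cyc, 100)
        assert np.allclose(out.theta, 4.0)

    def test_linear_ramp_interpolates_exactly(self):
        n = 123
        t = np.linspace(0.0, 2.0, n)
        cyc = Cycle(times=t, theta=3.0 * t + 1.0, delta=np.zeros(n),
                    duration=2.0, index_in_run=0)
        out = resample_cycle(cyc, 250)
        assert np.allclose(out.theta, 3.0 * out.times + 1.0, atol=1e-9)
        assert out.times[0] == t[0] and out.times[-1] == t[-1]

    def test_too_small_count_rejected(self):
        with pytest.raises(ValueError):
            resample_cycle(make_cycle(), 1)


class TestDTW:
    def test_identity_is_zero(self):
        x = np.random.default_rng(1).random((40, 2))
        assert dtw_dissimilarity(x, x) == 0.0

    def test_constant_offset_is_the_offset(self):
        a = np.zeros(250)
        b = np.full(250, 3.2)
        assert dtw_dissimilarity(a, b) == pytest.approx(3.2, abs=1e-9)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(1, 6, size=2)
            d = rng.random((n, m))
            assert normalized_dtw(d) == pytest.approx(
                brute_force_normalized_dtw(d), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dtw_dissimilarity(np.zeros((5, 2)), np.zeros((5, 3)))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
           st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, xs, ys):
        a, b = np.asarray(xs), np.asarray(ys)
        v = dtw_dissimilarity(a, b)
        assert v >= 0.0
        assert v == pytest.approx(dtw_dissimilarity(b, a), abs=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_zero_iff_warpable_match(self, xs):
        a = np.asarray(xs)
        # repeating samples is warpable onto the original at zero cost
        b = np.repeat(a, 2)
        assert dtw_dissimilarity(a, b) == pytest.approx(0.0, abs=1e-12)
        assert (dtw_dissimilarity(a, a + 1.0) > 0.0)


class TestMetrics:
    def test_cycles_identical_to_reference_score_zero(self, ref_cycle, config):
        cycles = [replace(ref_cycle, index_in_run=i) for i in range(4)]
        assert spatial_error(cycles, ref_cycle, config) == pytest.approx(0, abs=1e-9)
        assert velocity_error(cycles, ref_cycle, config) == pytest.approx(0, abs=1e-9)
        assert spatial_variability(cycles, config) == pytest.approx(0, abs=1e-9)
        assert velocity_variability(cycles, config) == pytest.approx(0, abs=1e-9)

    def test_constant_theta_shift_bounded_by_offset(self, ref_cycle, config):
        c = 1.7
        shifted = replace(ref_cycle, theta=ref_cycle.theta + c, index_in_run=0)
        v = spatial_error([shifted], ref_cycle, config)
        assert 0.0 < v <= c + 1e-12

    def test_two_constant_cycles_variability_is_offset(self, config):
        c = 2.5
        a = make_cycle(index=0)
        b = make_cycle(index=1, theta=np.full(250, c))
        assert spatial_variability([a, b], config) == pytest.approx(c, abs=1e-9)

    def test_variability_invariant_to_cycle_order(self, config):
        rng = np.random.default_rng(5)
        cycles = [make_cycle(index=i, theta=rng.normal(0, 1, 250))
                  for i in range(5)]
        v1 = spatial_variability(cycles, config)
        v2 = spatial_variability(cycles[::-1], config)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_uniform_speedup_hits_velocity_not_shape(self, spec, config):
        # Same spatial path rowed 1.1x faster: the resampled path is
        # unchanged but the speed profile magnitude scales up.
        ref = reference_cycle(spec, config)
        fast_dur = spec.period / 1.1
        u = np.linspace(0.0, (249 / 250), 250)
        from rowsim.reference import reference_waveform
        th, de = reference_waveform(u, spec)
        fast = Cycle(times=np.linspace(0, fast_dur * 249 / 250, 250),
                     theta=th, delta=de, duration=fast_dur, index_in_run=0)
        assert spatial_error([fast], ref, config) == pytest.approx(0.0, abs=1e-6)
        assert velocity_error([fast], ref, config) > 0.01

    def test_undefined_metrics_are_nan(self, ref_cycle, config):
        assert np.isnan(spatial_error([], ref_cycle, config))
        assert np.isnan(spatial_variability([make_cycle()], config))


class TestEvaluateRun:
    def test_noiseless_run_scores_below_tolerance(self, ref_traj_120, config):
        m = evaluate_run(ref_traj_120, config=config)
        assert m.spatial_error < 1e-6
        assert m.velocity_error < 1e-6
        assert m.spatial_variability < 1e-6
        assert m.velocity_variability < 1e-6
        assert (m.n_cycles_total, m.n_cycles_valid) == (48, 44)

    def test_out_of_band_cycles_removed_one_for_one(self, config):
        run = simulate_run(RowerProfile(spatial_noise_deg=0.2, outlier_rate=0.15,
                                        seed=9), duration=120.0)
        m = evaluate_run(run.trajectory, config=config)
        ends = np.cumsum(run.cycle_durations)
        complete = run.cycle_durations[ends <= 120.0 + 1e-9]
        assert m.n_cycles_total == len(complete)
        spm = 60.0 / complete[3:-1]
        expected_valid = int(np.sum((spm >= 22.0) & (spm <= 26.0)))
        assert m.n_cycles_valid == expected_valid
        assert m.n_cycles_valid < m.n_cycles_total - 4  # outliers were injected

    def test_metrics_invariant_to_time_translation(self, spec, config):
        run = simulate_run(RowerProfile(seed=21), duration=30.0)
        traj = run.trajectory
        shifted = Trajectory(times=traj.times + 17.3, theta=traj.theta,
                             delta=traj.delta, sample_rate=traj.sample_rate)
        m1 = evaluate_run(traj, config=config)
        m2 = evaluate_run(shifted, config=config)
        assert m1.spatial_error == pytest.approx(m2.spatial_error, rel=1e-12)
        assert m1.velocity_error == pytest.approx(m2.velocity_error, rel=1e-12)
        assert m1.spatial_variability == pytest.approx(
            m2.spatial_variability, rel=1e-12)
        assert m1.velocity_variability == pytest.approx(
            m2.velocity_variability, rel=1e-12)

    def test_pipeline_is_deterministic(self, config):
        run = simulate_run(RowerProfile(seed=3), duration=30.0)
        m1 = evaluate_run(run.trajectory, config=config)
        m2 = evaluate_run(run.trajectory, config=config)
        assert m1 == m2

    def test_empty_run_propagates_nan(self, spec, config):
        traj = generate_reference(spec, duration=2.0, sample_rate=100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = evaluate_run(traj, config=config)
        assert np.isnan(m.spatial_error) and np.isnan(m.velocity_variability)
        assert m.n_cycles_valid == 0
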