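"""Motility metrics: velocities, speeds, displacement, pauses, arrest coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_track, random_track
from ctltrack.compartments import SphereSurface
from ctltrack.metrics import (
    VelocitySeries,
    arrest_coefficient,
    detect_pauses,
    fraction_paused_cells,
    instantaneous_velocity,
    mean_track_speed,
    path_length,
    summarize_cohort,
    summarize_track,
    track_displacement_length,
)
from ctltrack.tracks import Track, TrackSet


def brute_force_pauses(speeds, threshold, dt, min_duration_s):
    """Independent run-length scan: list of (start, length) below-threshold runs."""
    runs, start = [], None
    for i, v in enumerate(list(speeds) + [np.inf]):
        if v < threshold and start is None:
            start = i
        elif v >= threshold and start is not None:
            if (i - start) * dt >= min_duration_s:
                runs.append((start, i - start))
            start = None
    return runs


class TestInstantaneousVelocity:
    def test_uniform_steps_give_constant_speed(self):
        tr = make_track([[2, 0, 0]] * 5)  # 2 um per 30 s = 4 um/min
        vs = instantaneous_velocity(tr)
        np.testing.assert_allclose(vs.speeds, 4.0)

    def test_stationary_track_all_zeros(self):
        tr = make_track([[0, 0, 0]] * 4)
        np.testing.assert_allclose(instantaneous_velocity(tr).speeds, 0.0)

    def test_3d_pythagorean_steps(self):
        tr = make_track([[3, 4, 0]] * 3)  # 5 um per 30 s = 10 um/min
        np.testing.assert_allclose(instantaneous_velocity(tr).speeds, 10.0)

    def test_single_position_track_warns_empty(self):
        tr = Track(track_id=0, positions=np.zeros((1, 3)), frames=[0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            vs = instantaneous_velocity(tr)
        assert len(vs) == 0

    def test_gap_does_not_fabricate_velocity(self):
        tr = Track(
            track_id=0,
            positions=np.array([[0, 0, 0], [2, 0, 0], [100, 0, 0], [102, 0, 0.0]]),
            frames=[0, 1, 10, 11],
        )
        vs = instantaneous_velocity(tr)
        assert len(vs) == 2  # one interval per contiguous segment
        np.testing.assert_allclose(vs.speeds, 4.0)


class TestSpeedAndDisplacement:
    def test_square_loop_speed_and_zero_displacement(self):
        tr = make_track([[2, 0, 0], [0, 2, 0], [-2, 0, 0], [0, -2, 0]])
        assert mean_track_speed(tr) == pytest.approx(4.0)
        assert track_displacement_length(tr) == pytest.approx(0.0)

    def test_straight_line_displacement(self):
        tr = make_track([[2, 0, 0]] * 10)
        assert track_displacement_length(tr) == pytest.approx(20.0)
        assert path_length(tr) == pytest.approx(20.0)

    def test_concatenation_mean_is_mean_of_halves(self, rng):
        steps_a = rng.uniform(-3, 3, size=(10, 3))
        steps_b = rng.uniform(-3, 3, size=(10, 3))
        whole = make_track(np.vstack([steps_a, steps_b]))
        a, b = make_track(steps_a), make_track(steps_b)
        assert mean_track_speed(whole) == pytest.approx(
            (mean_track_speed(a) + mean_track_speed(b)) / 2
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_displacement_never_exceeds_path(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_track(rng, n_intervals=int(rng.integers(1, 30)))
        assert track_displacement_length(tr) <= path_length(tr) + 1e-9

    def test_displacement_equals_path_iff_collinear_monotone(self):
        straight = make_track([[1, 1, 0]] * 5)
        assert track_displacement_length(straight) == pytest.approx(path_length(straight))
        backtrack = make_track([[1, 0, 0], [-1, 0, 0]])
        assert track_displacement_length(backtrack) < path_length(backtrack)


class TestPauses:
    def test_middle_run_detected(self):
        vs = VelocitySeries(0, [5, 3, 3, 5], dt=30.0)
        events = detect_pauses(vs, threshold=4.0)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(60.0)
        assert events[0].mean_speed == pytest.approx(3.0)

    def test_no_pause_when_all_fast(self):
        vs = VelocitySeries(0, [5, 6, 7], dt=30.0)
        assert detect_pauses(vs, threshold=4.0) == []

    def test_strict_inequality_at_threshold(self):
        vs = VelocitySeries(0, [4.0, 3.999], dt=30.0)
        events = detect_pauses(vs, threshold=4.0)
        assert len(events) == 1 and events[0].start_frame == 1

    def test_min_duration_filters_short_runs(self):
        vs = VelocitySeries(0, [1, 9, 1, 1, 9], dt=30.0)
        events = detect_pauses(vs, threshold=4.0, min_duration_s=60.0)
        assert [(e.start_frame, e.duration_s) for e in events] == [(2, 60.0)]

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_runlength_scan(self, seed):
        rng = np.random.default_rng(seed)
        speeds = rng.uniform(0, 8, size=int(rng.integers(1, 60)))
        thr = float(rng.uniform(0.5, 7.5))
        min_dur = float(rng.choice([30.0, 60.0, 90.0]))
        vs = VelocitySeries(0, speeds, dt=30.0)
        got = [(e.start_frame, int(e.duration_s / 30)) for e in
               detect_pauses(vs, thr, min_dur)]
        assert got == brute_force_pauses(speeds, thr, 30.0, min_dur)


class TestArrestCoefficient:
    def test_fraction_below_threshold(self):
        vs = VelocitySeries(0, [1, 1, 1, 1, 9, 9, 9, 9, 9, 9], dt=30.0)
        assert arrest_coefficient(vs, threshold=4.0) == pytest.approx(0.4)

    def test_extremes(self):
        assert arrest_coefficient(VelocitySeries(0, [1, 2], 30.0), 4.0) == 1.0
        assert arrest_coefficient(VelocitySeries(0, [5, 6], 30.0), 4.0) == 0.0

    def test_empty_series_is_missing_not_zero(self):
        assert np.isnan(arrest_coefficient(VelocitySeries(0, [], 30.0), 4.0))

    def test_monotone_in_threshold(self, rng):
        speeds = rng.uniform(0, 10, size=50)
        vs = VelocitySeries(0, speeds, 30.0)
        coeffs = [arrest_coefficient(vs, thr) for thr in (1, 2, 4, 6, 8)]
        assert coeffs == sorted(coeffs)

    def test_converges_to_markov_stationary_fraction(self):
        # long two-state track with zero positional noise: the measured
        # arrest coefficient must converge to the stationary arrest
        # probability within 3 binomial SEs
        from ctltrack.simulate import MotilityParams, Scenario, GroupSpec, generate_cohort

        pi_a = 0.4
        params = MotilityParams(
            mean_speed=6.0, arrest_fraction=pi_a, arrested_speed=1.0, noise_sigma=0.0
        )
        spec = GroupSpec(
            "WT", 10,
            {"infiltrating": 1.0, "approaching": 0.0, "peripheral": 0.0},
            {k: params for k in ("infiltrating", "approaching", "peripheral")},
        )
        sc = Scenario(
            name="long", model="DSFC", tumor="PancOVA", groups=(spec,),
            n_frames=1001, tumor_radius=150.0,
        )
        ts, _ = generate_cohort(sc, seed=5)
        n_total = sum(t.n_intervals for t in ts)
        coeff = np.mean(
            [arrest_coefficient(instantaneous_velocity(t), 4.0) for t in ts]
        )
        se = np.sqrt(pi_a * (1 - pi_a) / n_total)
        # dwell times correlate consecutive intervals; inflate SE by the
        # integrated autocorrelation of a two-state chain
        lam = 1 - (0.25 + 0.25 * (1 - pi_a) / pi_a)
        tau = (1 + lam) / (1 - lam)
        assert abs(coeff - pi_a) <= 3 * se * np.sqrt(tau)


class TestFractionPaused:
    def test_share_of_tracks_with_pauses(self):
        series = [
            VelocitySeries(0, [1, 5], 30.0),
            VelocitySeries(1, [5, 1], 30.0),
            VelocitySeries(2, [5, 5], 30.0),
        ]
        assert fraction_paused_cells(series, 4.0) == pytest.approx(66.6667, abs=1e-3)

    def test_monotone_in_threshold(self, rng):
        series = [VelocitySeries(i, rng.uniform(0, 10, 20), 30.0) for i in range(30)]
        fracs = [fraction_paused_cells(series, thr) for thr in (0.5, 2, 4, 8)]
        assert fracs == sorted(fracs)


class TestSummaries:
    def test_stationary_in_sphere_track(self):
        surface = SphereSurface(center=(0, 0, 0), radius=50.0)
        tr = make_track([[0, 0, 0]] * 5, start=(10, 0, 0))
        s = summarize_track(tr, surface, threshold=4.0)
        assert s.mean_track_speed == 0.0
        assert s.track_displacement_length == 0.0
        assert s.arrest_coefficient == 1.0
        assert s.compartment == "infiltrating"

    def test_fast_straight_escape_track(self):
        surface = SphereSurface(center=(0, 0, 0), radius=50.0)
        tr = make_track([[5, 0, 0]] * 10, start=(45, 0, 0))  # 10 um/min
        s = summarize_track(tr, surface, threshold=4.0)
        assert s.arrest_coefficient == 0.0
        assert s.n_pauses == 0

    def test_cohort_summary_matches_per_op_results(self, rng):
        surface = SphereSurface(center=(50, 50, 50), radius=40.0)
        ts = TrackSet(tracks=[random_track(rng, n_intervals=12, track_id=i)
                              for i in range(10)])
        df = summarize_cohort(ts, surface, threshold=4.0, min_intervals=0)
        for tr in ts:
            row = df[df.track_id == tr.track_id].iloc[0]
            assert row.mean_track_speed == pytest.approx(mean_track_speed(tr))
            assert row.track_displacement_length == pytest.approx(
                track_displacement_length(tr)
            )
            assert row.arrest_coefficient == pytest.approx(
                arrest_coefficient(instantaneous_velocity(tr), 4.0)
            )

    def test_min_intervals_filter(self, rng):
        short = random_track(rng, n_intervals=2, track_id=0)
        long = random_track(rng, n_intervals=10, track_id=1)
        df = summarize_cohort(TrackSet(tracks=[short, long]), min_intervals=4)
        assert df.track_id.tolist() == [1]
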