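"""Synthetic cohort generator: calibration, determinism, boundaries, presets."""

import numpy as np
import pytest

from ctltrack.compartments import SphereSurface, classify_points
from ctltrack.metrics import arrest_coefficient, instantaneous_velocity
from ctltrack.simulate import (
    CalibrationError,
    GroupSpec,
    MotilityParams,
    Scenario,
    VolumeScenario,
    calibrate_states,
    expected_observed_speed,
    generate_cohort,
    generate_volumes,
    load_scenario,
    save_scenario,
    scenario_presets,
)
from ctltrack.kinetics import relative_volume


def uniform_group(name="WT", n=20, mean_speed=6.0, arrest=0.4, **pkw):
    params = MotilityParams(mean_speed=mean_speed, arrest_fraction=arrest, **pkw)
    return GroupSpec(
        name, n,
        {"infiltrating": 0.4, "approaching": 0.3, "peripheral": 0.3},
        {k: params for k in ("infiltrating", "approaching", "peripheral")},
    )


def tiny_scenario(**kwargs):
    defaults = dict(
        name="tiny", model="DSFC", tumor="PancOVA",
        groups=(uniform_group(),), n_frames=21,
    )
    defaults.update(kwargs)
    return Scenario(**defaults)


class TestCalibration:
    def test_linear_mixture_without_noise(self):
        cal = calibrate_states(
            MotilityParams(mean_speed=4.0, arrest_fraction=0.5,
                           arrested_speed=0.0, noise_sigma=0.0)
        )
        assert cal.motile_speed == pytest.approx(8.0)

    def test_no_arrest_means_motile_equals_target(self):
        cal = calibrate_states(
            MotilityParams(mean_speed=5.0, arrest_fraction=0.0, noise_sigma=0.0)
        )
        assert cal.motile_speed == pytest.approx(5.0)
        assert cal.p_motile_to_arrested == 0.0

    def test_stationary_fraction_identity(self):
        cal = calibrate_states(MotilityParams(mean_speed=6.0, arrest_fraction=0.37))
        assert cal.stationary_arrest_fraction == pytest.approx(0.37)

    def test_infeasible_target_raises(self):
        with pytest.raises(CalibrationError, match="not reachable"):
            calibrate_states(
                MotilityParams(mean_speed=1.0, arrest_fraction=0.5, arrested_speed=1.0)
            )

    def test_noise_floor_inversion_validated_by_monte_carlo(self):
        # simulate 1e5 intervals at the calibrated parameters: observed mean
        # speed must land within 1% of the target
        target = 4.0
        params = MotilityParams(mean_speed=target, arrest_fraction=0.5,
                                arrested_speed=1.0, noise_sigma=0.3)
        cal = calibrate_states(params)
        rng = np.random.default_rng(0)
        n = 100_000
        arrested = rng.random(n) < params.arrest_fraction
        speed = np.where(arrested, params.arrested_speed, cal.motile_speed)
        step = speed * 30.0 / 60.0
        true_steps = np.zeros((n, 3))
        true_steps[:, 0] = step
        noise = rng.normal(0, params.noise_sigma * np.sqrt(2), size=(n, 3))
        observed = np.linalg.norm(true_steps + noise, axis=1) * 2.0
        assert observed.mean() == pytest.approx(target, rel=0.01)

    def test_expected_observed_speed_reduces_to_identity_without_noise(self):
        for v in (0.0, 1.0, 7.3):
            assert expected_observed_speed(v, 0.0, 30.0) == pytest.approx(v)


class TestGenerateCohort:
    def test_seed_determinism(self):
        sc = tiny_scenario()
        a, ta = generate_cohort(sc, seed=9)
        b, tb = generate_cohort(sc, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)
        assert ta.equals(tb)

    def test_different_seeds_differ(self):
        sc = tiny_scenario()
        a, _ = generate_cohort(sc, seed=1)
        b, _ = generate_cohort(sc, seed=2)
        assert not np.allclose(a.tracks[0].positions, b.tracks[0].positions)

    def test_all_arrested_limit_gives_unit_arrest_coefficients(self):
        params = MotilityParams(mean_speed=0.0, arrest_fraction=1.0,
                                arrested_speed=0.0, noise_sigma=0.0)
        spec = GroupSpec(
            "WT", 10,
            {"infiltrating": 1.0, "approaching": 0.0, "peripheral": 0.0},
            {k: params for k in ("infiltrating", "approaching", "peripheral")},
        )
        sc = tiny_scenario(groups=(spec,))
        ts, truth = generate_cohort(sc, seed=4)
        for tr in ts:
            assert arrest_coefficient(instantaneous_velocity(tr), 4.0) == 1.0
        assert (truth.true_arrest_fraction == 1.0).all()

    def test_tracks_confined_to_field_and_compartment(self):
        sc = tiny_scenario()
        ts, truth = generate_cohort(sc, seed=6)
        surface = sc.surface
        extent = np.asarray(sc.field_extent)
        noise = 0.3
        by_id = truth.set_index("track_id")
        for tr in ts:
            # observed = true + noise; allow a generous noise margin
            assert (tr.positions >= -6 * noise).all()
            assert (tr.positions <= extent + 6 * noise).all()
            d = surface.signed_distance(tr.positions)
            comp = by_id.loc[tr.track_id, "compartment"]
            margin = 6 * noise
            if comp == "infiltrating":
                assert (d <= margin).all()
            elif comp == "approaching":
                assert ((d >= -margin) & (d <= sc.approach_band + margin)).all()
            else:
                assert (d >= sc.approach_band - margin).all()

    def test_placement_fractions_respected_exactly(self):
        sc = tiny_scenario()
        _, truth = generate_cohort(sc, seed=2)
        counts = truth.compartment.value_counts()
        assert counts["infiltrating"] == 8  # 0.4 * 20
        assert counts["approaching"] == 6
        assert counts["peripheral"] == 6

    def test_high_persistence_gives_straight_tracks(self):
        params = MotilityParams(mean_speed=8.0, arrest_fraction=0.0,
                                noise_sigma=0.0, persistence=5000.0)
        spec = GroupSpec(
            "WT", 15,
            {"infiltrating": 0.0, "approaching": 0.0, "peripheral": 1.0},
            {k: params for k in ("infiltrating", "approaching", "peripheral")},
        )
        sc = tiny_scenario(groups=(spec,), n_frames=11)
        ts, _ = generate_cohort(sc, seed=3)
        from ctltrack.metrics import path_length, track_displacement_length

        ratios = [
            track_displacement_length(t) / path_length(t)
            for t in ts
        ]
        # boundary bounces can bend a track; the bulk must be nearly straight
        assert np.median(ratios) > 0.99

    def test_stationary_occupancy_matches_arrest_fraction(self):
        sc = tiny_scenario(groups=(uniform_group(n=60, arrest=0.3),), n_frames=61)
        _, truth = generate_cohort(sc, seed=8)
        occ = truth.true_arrest_fraction.mean()
        n_int = truth.n_intervals.sum()
        se = np.sqrt(0.3 * 0.7 / n_int)
        assert abs(occ - 0.3) <= 3 * se * np.sqrt(5)  # dwell-time autocorrelation


class TestVolumes:
    def test_zero_cv_hits_target_exactly(self):
        vsc = VolumeScenario(name="v", targets={"WT": 100.0}, cv=0.0)
        vols = generate_volumes(vsc, seed=1, n_spheroids=10)
        for v in vols:
            assert relative_volume(v) == pytest.approx(100.0)

    def test_law_of_large_numbers_at_target(self):
        vsc = VolumeScenario(name="v", targets={"Il1r_ko": 47.0}, cv=0.10)
        vols = generate_volumes(vsc, seed=2, n_spheroids=1000)
        mean = np.mean([relative_volume(v) for v in vols])
        assert mean == pytest.approx(47.0, rel=0.01)


class TestPresets:
    def test_preset_inventory(self):
        presets = scenario_presets()
        assert len(presets) >= 6
        models = {s.model for s in presets.values() if isinstance(s, Scenario)}
        assert models == {"DSFC", "spheroid"}
        tumors = {s.tumor for s in presets.values() if isinstance(s, Scenario)}
        assert tumors == {"Panc02", "PancOVA"}

    def test_every_preset_calibrates(self):
        for preset in scenario_presets().values():
            if not isinstance(preset, Scenario):
                continue
            for g in preset.groups:
                for params in g.params.values():
                    cal = calibrate_states(params, preset.dt)
                    assert cal.motile_speed > 0
                    assert 0 <= cal.p_motile_to_arrested <= 1
                    assert 0 <= cal.p_arrested_to_motile <= 1

    def test_presets_roundtrip_through_config_files(self, tmp_path):
        for name, preset in scenario_presets().items():
            p = tmp_path / f"{name}.yaml"
            save_scenario(preset, p)
            assert load_scenario(p) == preset

    def test_spheroid_presets_use_lower_threshold(self):
        presets = scenario_presets()
        assert presets["dsfc_pancova"].pause_threshold == 4.0
        assert presets["spheroid_pancova_late"].pause_threshold == 2.0
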