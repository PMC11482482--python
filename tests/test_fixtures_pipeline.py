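"""Synthetic reference generators, the end-to-end case driver, config I/O
and the command-line interface."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import ablasim as ab
from ablasim.config import config_from_dict, load_config, save_config
from ablasim.fixtures import SyntheticSensorSpec, SyntheticZoneSpec


class TestSyntheticZone:
    def test_sphere_volume_analytic(self):
        spec = SyntheticZoneSpec(half_axes=(10.0, 10.0, 10.0), voxel_spacing=0.5)
        vol = ab.generate_reference_zone(spec)
        analytic = 4 / 3 * np.pi * 10e-3**3
        assert vol.volume == pytest.approx(analytic, rel=0.02)

    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticZoneSpec(jitter_amplitude=1.0, seed=7)
        a = ab.generate_reference_zone(spec)
        b = ab.generate_reference_zone(spec)
        assert np.array_equal(a.mask, b.mask)

    def test_different_seed_changes_jittered_mask(self):
        a = ab.generate_reference_zone(SyntheticZoneSpec(jitter_amplitude=1.0, seed=1))
        b = ab.generate_reference_zone(SyntheticZoneSpec(jitter_amplitude=1.0, seed=2))
        assert not np.array_equal(a.mask, b.mask)

    def test_vessel_defect_is_a_through_hole(self):
        """No mask voxels remain on the defect cylinder's axis line."""
        spec = SyntheticZoneSpec(half_axes=(10.0, 10.0, 10.0),
                                 vessel_defect=(2.0, "z", 0.0), voxel_spacing=0.5)
        vol = ab.generate_reference_zone(spec)
        centers = vol.voxel_centers()
        on_axis = np.hypot(centers[:, 0] - 0.0, centers[:, 1]) < 1.9e-3
        assert vol.voxel_count > 0
        assert not on_axis.any()

    def test_spacing_coarser_than_half_axis_rejected(self):
        with pytest.raises(ValueError):
            SyntheticZoneSpec(half_axes=(1.0, 10.0, 10.0), voxel_spacing=2.0)


class TestSyntheticSensors:
    def test_noise_free_closed_form(self):
        spec = SyntheticSensorSpec(asymptotic_temperature=80.0, initial_temperature=20.0,
                                   time_constant=100.0, noise_std=0.0, sample_interval=1.0)
        df = ab.generate_sensor_series(spec)
        assert df["temperature_C"].iloc[0] == pytest.approx(20.0)
        at_tau = df.loc[df["time_s"] == 100.0, "temperature_C"].iloc[0]
        assert at_tau == pytest.approx(20.0 + 60.0 * (1 - np.exp(-1)))
        assert df["temperature_C"].is_monotonic_increasing

    def test_seeded_noise_reproducible(self):
        spec = SyntheticSensorSpec(noise_std=0.5, seed=3)
        a, b = ab.generate_sensor_series(spec), ab.generate_sensor_series(spec)
        pd.testing.assert_frame_equal(a, b)


class TestRunCase:
    def test_rerun_is_bit_identical(self, coarse_phantom_config, coarse_phantom_result):
        again = ab.run_case(coarse_phantom_config)
        assert np.array_equal(again.sar.q_ext, coarse_phantom_result.sar.q_ext)
        assert np.array_equal(again.history.final, coarse_phantom_result.history.final)
        assert np.array_equal(again.damage_field.omega, coarse_phantom_result.damage_field.omega)

    def test_bundle_contains_both_zone_models(self, coarse_phantom_result):
        res = coarse_phantom_result
        assert res.arrhenius_mask.dtype == bool and res.critical_mask.dtype == bool
        assert res.arrhenius_volume is not None and res.arrhenius_volume.voxel_count > 0
        assert res.critical_volume is not None
        assert {"time_s", "r10mm_z18mm"} <= set(res.probes.columns)

    def test_clinical_case_activates_perfusion_and_warm_coolant(self):
        cfg = ab.CaseConfig.clinical()
        assert cfg.thermal.include_perfusion and cfg.thermal.include_metabolic
        assert cfg.thermal.coolant_temperature == 20.0
        assert cfg.em.input_power == 42.0
        short = replace(cfg, grid_policy=ab.GridPolicy.coarse(),
                        thermal=replace(cfg.thermal, duration=30.0))
        res = ab.run_case(short)
        assert "tumor" in res.grid.material_names
        assert res.history.peak_temperature() > 37.0

    def test_zero_duration_degenerates_gracefully(self, coarse_phantom_config):
        cfg = replace(coarse_phantom_config,
                      thermal=replace(coarse_phantom_config.thermal, duration=0.0))
        res = ab.run_case(cfg)
        assert not res.arrhenius_mask.any()
        assert res.arrhenius_volume is None
        assert res.metrics is None

    def test_self_consistency_dice(self, coarse_phantom_result):
        """A reference rebuilt from the simulated zone's own contour (no
        jitter, identity transform) overlaps it up to voxelization error."""
        res = coarse_phantom_result
        contour = ab.extract_contour(res.arrhenius_mask.astype(float),
                                     res.grid.r_centers, res.grid.z_centers, 0.5)
        reference = ab.revolve(contour, voxel_spacing=res.config.voxel_spacing)
        rep = ab.compute_metrics(res.arrhenius_volume, reference,
                                 ab.RigidTransform.identity())
        assert rep.dice >= 0.98
        # a mismatched voxel pitch adds nearest-neighbour resampling error
        rep_cross = ab.compute_metrics(
            res.arrhenius_volume, ab.revolve(contour, voxel_spacing=0.4e-3),
            ab.RigidTransform.identity())
        assert rep_cross.dice >= 0.95

    def test_metrics_against_synthetic_reference(self, coarse_phantom_config):
        ref = ab.generate_reference_zone(SyntheticZoneSpec(half_axes=(12.0, 12.0, 14.0),
                                                           center=(0.0, 0.0, 25.0)))
        res = ab.run_case(coarse_phantom_config, reference=ref)
        assert res.metrics is not None
        assert 0.0 <= res.metrics.dice <= 1.0
        assert res.metrics.hausdorff_mm >= res.metrics.mean_euclidean_mm >= 0.0

    def test_stage_failures_are_labelled(self):
        cfg = replace(ab.CaseConfig.phantom(), material_overrides={"sigma_phantom": 0.0})
        with pytest.raises(RuntimeError, match="'em'"):
            ab.run_case(cfg)

    def test_bundle_write(self, tmp_path, coarse_phantom_result):
        out = coarse_phantom_result.write(tmp_path / "run")
        for name in ("probes.csv", "fields.npz", "manifest.json", "zone_arrhenius.nii"):
            assert (out / name).exists(), name
        data = np.load(out / "fields.npz")
        assert data["q_ext"].shape == coarse_phantom_result.sar.q_ext.shape


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = replace(ab.CaseConfig.clinical(), material_overrides={"sigma_liver": 1.75},
                      voxel_spacing=0.4e-3)
        path = tmp_path / "case.yaml"
        save_config(cfg, path)
        again = load_config(path)
        assert again == cfg

    def test_sections_override_defaults(self):
        cfg = config_from_dict({
            "case": "phantom",
            "em": {"input_power": 30.0},
            "thermal": {"duration": 120.0},
            "needle": {"slot_width": 0.8e-3},
            "materials": {"sigma_phantom": 1.5},
        })
        assert cfg.em.input_power == 30.0
        assert cfg.thermal.duration == 120.0
        assert cfg.needle.slot_width == 0.8e-3
        assert cfg.material_overrides == {"sigma_phantom": 1.5}

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            config_from_dict({"em": {"inpt_power": 30.0}})


class TestCLI:
    def test_fixture_commands(self, tmp_path):
        from click.testing import CliRunner

        from ablasim.cli import main

        runner = CliRunner()
        out = runner.invoke(main, ["fixtures", "sensors", "--noise", "0.2", "--seed", "5",
                                   "--out", str(tmp_path / "sensors.csv")])
        assert out.exit_code == 0, out.output
        df = pd.read_csv(tmp_path / "sensors.csv")
        assert {"time_s", "temperature_C"} <= set(df.columns)

        out = runner.invoke(main, ["fixtures", "zone", "--spacing", "1.0",
                                   "--out", str(tmp_path / "zone.nii")])
        assert out.exit_code == 0, out.output

    def test_metrics_command_identity(self, tmp_path):
        from click.testing import CliRunner

        from ablasim.cli import main

        vol = ab.generate_reference_zone(SyntheticZoneSpec(voxel_spacing=1.0))
        vol.to_nifti(str(tmp_path / "a.nii"))
        runner = CliRunner()
        out = runner.invoke(main, ["metrics", "--sim-zone", str(tmp_path / "a.nii"),
                                   "--reference", str(tmp_path / "a.nii"),
                                   "--out", str(tmp_path / "report.json")])
        assert out.exit_code == 0, out.output
        import json

        report = json.loads((tmp_path / "report.json").read_text())
        assert report["dice"] == pytest.approx(1.0)
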