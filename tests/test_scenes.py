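"""Synthetic scene generator: validation, ground truth, noise model, I/O."""

import dataclasses

import numpy as np
import pytest

from acquant import scenes
from acquant.scenes import Noise, Protrusion, SceneSpec, SceneSpecError

from conftest import compact_spec


class TestSpecValidation:
    def test_rejects_landmark_outside_grid_naming_it(self):
        with pytest.raises(SceneSpecError, match="vulF_mid"):
            compact_spec(
                landmarks={
                    "vulA1": (1.0, 3.8),
                    "vulA2": (7.0, 3.8),
                    "ac_edge_1": (3.3, 1.6),
                    "ac_edge_2": (4.7, 1.6),
                    "vulF_mid": (40.0, 4.2),
                }
            )

    def test_rejects_protrusion_through_intact_bm(self):
        with pytest.raises(SceneSpecError, match="intact BM"):
            compact_spec(bm_gap_width_um=0.0)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_frames": 0},
            {"voxel_size": (0.25, -0.1, 0.1)},
            {"ac_radii": (0.0, 0.9, 0.9)},
            {"bm_gap_width_um": -1.0},
        ],
    )
    def test_rejects_invalid_scalars(self, overrides):
        with pytest.raises(SceneSpecError):
            compact_spec(**overrides)

    def test_rejects_stalk_wider_than_gap(self):
        with pytest.raises(SceneSpecError, match="gap"):
            compact_spec(protrusion=Protrusion(True, stalk_radius_um=1.5, length_um=0.8))


class TestBuildScene:
    def test_no_protrusion_means_zero_true_volume(self, small_spec):
        spec = dataclasses.replace(small_spec, protrusion=Protrusion(present=False))
        _, truth = scenes.build_scene(spec)
        assert truth.true_volume_trace[0][1] == 0.0

    def test_true_volume_matches_exhaustive_membership_count(self):
        # independent oracle: per-voxel-center membership test of the
        # stalk+cap solid, evaluated in a plain python loop
        spec = SceneSpec(
            grid_shape=(60, 70, 60),
            voxel_size=(0.1, 0.1, 0.1),
            ac_center=(3.0, 2.0, 3.0),
            ac_radii=(1.2, 1.0, 1.0),
            protrusion=Protrusion(True, stalk_radius_um=0.5, length_um=2.0),
            bm_y_um=3.5,
            bm_gap_center_um=3.0,
            bm_gap_width_um=1.4,
            landmarks={
                "vulA1": (1.0, 4.5),
                "vulA2": (5.0, 4.5),
                "ac_edge_1": (2.5, 1.5),
                "ac_edge_2": (3.5, 1.5),
                "vulF_mid": (3.0, 5.0),
            },
        )
        _, truth = scenes.build_scene(spec)
        cx, _, cz = spec.ac_center
        r = 0.5
        tip = spec.bm_y_um + 2.0
        count = 0
        for iz in range(60):
            z = (iz + 0.5) * 0.1
            for iy in range(70):
                y = (iy + 0.5) * 0.1
                for ix in range(60):
                    x = (ix + 0.5) * 0.1
                    radial = (x - cx) ** 2 + (z - cz) ** 2 <= r**2
                    in_stalk = radial and spec.bm_y_um < y <= tip
                    in_cap = (
                        y > tip
                        and (x - cx) ** 2 + (z - cz) ** 2 + (y - tip) ** 2 <= r**2
                    )
                    if in_stalk or in_cap:
                        count += 1
        assert truth.true_volume_trace[0][1] == pytest.approx(count * 0.001, abs=1e-12)

    def test_centered_landmarks_give_true_alignment_half_and_zero(self, small_spec):
        _, truth = scenes.build_scene(small_spec)
        assert truth.true_r_a == pytest.approx(0.5)
        assert truth.true_delta_um == pytest.approx(0.0)

    def test_channels_carry_expected_structures(self, small_spec):
        scene, _ = scenes.build_scene(small_spec)
        assert scene.shape == (2, 16, 48, 80)
        # AC channel bright at the AC center voxel
        assert scene[0, 8, 20, 40] > small_spec.background
        # BM channel bright on the sheet away from the gap, dark inside it
        assert scene[1, 8, 30, 10] > 100
        assert scene[1, 8, 30, 40] < 100


class TestRenderStack:
    def test_degenerate_forward_model_is_identity_up_to_quantization(self, small_spec):
        spec = dataclasses.replace(
            small_spec, noise=Noise(photon_gain=0.0, read_sd=0.0), psf_sigma_um=(1e-3, 1e-3)
        )
        scene, _ = scenes.build_scene(spec)
        obs = scenes.render_stack(scene, spec)
        assert np.abs(obs.astype(float) - scene).max() <= 0.5 + 1e-9

    def test_same_seed_bit_identical(self, small_spec):
        a = scenes.render_stack(scenes.build_scene(small_spec)[0], small_spec)
        b = scenes.render_stack(scenes.build_scene(small_spec)[0], small_spec)
        assert np.array_equal(a, b)

    def test_uniform_patch_variance_matches_noise_model(self):
        # variance ~= gain * mean + read_sd^2 on a uniform 64x64 patch
        spec = compact_spec(
            grid_shape=(4, 80, 80),
            noise=Noise(photon_gain=4.0, read_sd=2.0),
            psf_sigma_um=(1e-3, 1e-3),
            bm_gap_width_um=2.0,
        )
        scene = np.full((1, 4, 80, 80), 200.0)
        obs = scenes.render_stack(scene, spec).astype(float)
        patch = obs[0, 2, 8:72, 8:72]
        expected = 4.0 * 200.0 + 2.0**2
        assert patch.var() == pytest.approx(expected, rel=0.10)

    def test_quadrupled_photon_flux_halves_relative_shot_noise(self):
        scene = np.full((1, 4, 80, 80), 400.0)
        rel = []
        for gain in (4.0, 1.0):  # gain/4 = 4x the photons per intensity unit
            spec = compact_spec(
                grid_shape=(4, 80, 80),
                noise=Noise(photon_gain=gain, read_sd=0.0),
                psf_sigma_um=(1e-3, 1e-3),
            )
            patch = scenes.render_stack(scene, spec).astype(float)[0, 2, 8:72, 8:72]
            rel.append(patch.std() / patch.mean())
        assert rel[0] / rel[1] == pytest.approx(2.0, rel=0.1)


class TestTimeSeries:
    def test_static_series_frames_identical_in_truth_and_geometry(self, small_spec):
        spec = dataclasses.replace(
            small_spec, n_frames=3, noise=Noise(photon_gain=0.0, read_sd=0.0)
        )
        ts = scenes.simulate_timeseries(spec)
        assert np.array_equal(ts.frames[0], ts.frames[1])
        assert np.array_equal(ts.frames[1], ts.frames[2])
        vols = [v for _, v in ts.truth.true_volume_trace]
        assert vols[0] == vols[1] == vols[2]

    def test_linear_growth_gives_strictly_increasing_true_volumes(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            n_frames=4,
            frame_interval_s=300.0,
            protrusion=Protrusion(True, 0.6, 0.8, growth_um_per_min=0.02),
        )
        ts = scenes.simulate_timeseries(spec)
        vols = np.array([v for _, v in ts.truth.true_volume_trace])
        assert np.all(np.diff(vols) > 0)

    def test_determinism_and_jitter_bookkeeping(self, small_spec):
        spec = dataclasses.replace(small_spec, n_frames=4, jitter_vox=2, seed=5)
        a = scenes.simulate_timeseries(spec)
        b = scenes.simulate_timeseries(spec)
        assert np.array_equal(a.frames, b.frames)
        assert a.truth.applied_shifts == b.truth.applied_shifts
        assert a.truth.applied_shifts[0] == (0, 0)
        assert len(a.truth.applied_shifts) == 4

    def test_requires_two_frames(self, small_spec):
        with pytest.raises(SceneSpecError):
            scenes.simulate_timeseries(small_spec)


class TestFixtureIO:
    def test_round_trip_values_spec_and_truth(self, small_spec, tmp_path):
        spec = dataclasses.replace(small_spec, n_frames=2)
        ts = scenes.simulate_timeseries(spec)
        scenes.write_fixture(ts.frames, spec, ts.truth, tmp_path / "fx")
        back = scenes.read_fixture(tmp_path / "fx")
        assert np.array_equal(back.frames, ts.frames)
        assert back.spec == spec
        assert back.truth == ts.truth

    def test_missing_sidecar_is_explicit_state_not_failure(self, small_spec, tmp_path):
        scene, truth = scenes.build_scene(small_spec)
        obs = scenes.render_stack(scene, small_spec)
        scenes.write_fixture(obs, small_spec, truth, tmp_path / "fx")
        (tmp_path / "fx" / "ground_truth.json").unlink()
        back = scenes.read_fixture(tmp_path / "fx")
        assert back.truth is None and back.spec is None
        assert back.frames.shape == (1, 2, 16, 48, 80)
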