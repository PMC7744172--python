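"""Unit and property tests for phantom generation and acquisition simulation."""

import math

import numpy as np
import pytest

from lightcore.phantom import (
    NOISELESS,
    AcquisitionGeometry,
    BiopsyPhantom,
    GlandSpec,
    NoiseParams,
    RawStack,
    generate_phantom,
    load_phantom,
    load_stack,
    save_phantom,
    save_stack,
    simulate_acquisition,
)

from conftest import brute_force_frames, delta_phantom


class TestGlandSpec:
    def test_benign_requires_two_layers(self):
        with pytest.raises(ValueError, match="2 nuclear layers"):
            GlandSpec(center=(0, 0, 0), kind="benign", lumen_radius=10,
                      n_layers=1, nucleus_radius=3)

    def test_cancer_requires_one_layer(self):
        with pytest.raises(ValueError, match="1 nuclear layer"):
            GlandSpec(center=(0, 0, 0), kind="gleason3", lumen_radius=10,
                      n_layers=2, nucleus_radius=3)

    def test_lumen_must_exceed_nucleus(self):
        with pytest.raises(ValueError, match="lumen_radius"):
            GlandSpec(center=(0, 0, 0), kind="gleason3", lumen_radius=2,
                      n_layers=1, nucleus_radius=3)

    def test_gleason4_needs_partner(self):
        with pytest.raises(ValueError, match="fused partner"):
            GlandSpec(center=(0, 0, 0), kind="gleason4", lumen_radius=10,
                      n_layers=1, nucleus_radius=3)


class TestGeneratePhantom:
    def test_empty_mix_is_uniform_benign(self):
        ph = generate_phantom(100, 100, 40, {}, 2.0, seed=0)
        assert ph.truth_label == "benign"
        assert np.all(ph.volume == ph.volume.flat[0])  # uniform background
        assert np.all(ph.labels == 0)

    def test_determinism(self):
        a = generate_phantom(300, 200, 80, {"benign": 2, "gleason3": 1},
                             2.0, seed=7)
        b = generate_phantom(300, 200, 80, {"benign": 2, "gleason3": 1},
                             2.0, seed=7)
        np.testing.assert_array_equal(a.volume, b.volume)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.glands == b.glands

    def test_different_seeds_differ(self):
        a = generate_phantom(300, 200, 80, {"benign": 2}, 2.0, seed=1)
        b = generate_phantom(300, 200, 80, {"benign": 2}, 2.0, seed=2)
        assert not np.array_equal(a.volume, b.volume)

    def test_truth_label_cancer_iff_cancer_gland(self):
        benign = generate_phantom(300, 200, 80, {"benign": 2}, 2.0, seed=0)
        cancer = generate_phantom(300, 200, 80, {"gleason3": 1}, 2.0, seed=0)
        assert benign.truth_label == "benign"
        assert cancer.truth_label == "cancer"

    def test_depth_restricted_cancer(self):
        """Depth-confined lesion: all cancer voxels lie at z >= 60 um."""
        ph = generate_phantom(
            400, 200, 100, {"benign": 2, "gleason3": 1}, 2.0, seed=3,
            lumen_radius_um=8.0, cancer_lumen_radius_um=4.0,
            nucleus_radius_um=2.0, cancer_depth_range_um=(60.0, 80.0),
        )
        cancer_z = np.nonzero(np.any(ph.labels == 2, axis=(1, 2)))[0]
        assert cancer_z.size > 0
        assert cancer_z.min() * ph.voxel_pitch >= 60.0
        assert cancer_z.max() * ph.voxel_pitch <= 80.0
        for g in ph.glands:
            if g.is_cancer:
                assert g.depth_range[0] >= 60.0
                assert g.depth_range[1] <= 80.0

    def test_intensity_nonnegative_and_benign_glands_present(self):
        ph = generate_phantom(300, 200, 80, {"benign": 2}, 2.0, seed=0)
        assert np.all(ph.volume >= 0)
        assert np.any(ph.labels == 1)

    def test_gleason4_fusion_symmetric(self):
        ph = generate_phantom(600, 300, 100, {"gleason4": 2}, 2.0, seed=5)
        g0, g1 = ph.glands
        assert g0.fused_partners == (1,)
        assert g1.fused_partners == (0,)

    def test_single_gleason4_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_phantom(600, 300, 100, {"gleason4": 1}, 2.0, seed=0)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError, match="zero-size|positive"):
            generate_phantom(300, 200, 1.0, {}, 2.0, seed=0)

    def test_oversize_gland_rejected_with_identity(self):
        with pytest.raises(ValueError, match="gland 0"):
            generate_phantom(300, 30, 30, {"benign": 1}, 2.0, seed=0)

    def test_coarse_voxel_pitch_rejected(self):
        with pytest.raises(ValueError, match="nucleus radius"):
            generate_phantom(300, 200, 80, {"benign": 1}, 5.0, seed=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown gland kinds"):
            generate_phantom(300, 200, 80, {"gleason5": 1}, 2.0, seed=0)


class TestSimulateAcquisition:
    def test_uniform_phantom_noiseless(self, small_geometry):
        """Constant phantom: frames equal background x attenuation profile."""
        ph = generate_phantom(100, 60, 100, {}, 2.0, seed=0)
        background = ph.volume.flat[0]
        noise = NoiseParams(photon_scale=None, read_noise_sd=0.0,
                            attenuation_length_um=100.0)
        stack = simulate_acquisition(ph, small_geometry, noise, seed=0)
        p = small_geometry.binned_pitch
        theta = small_geometry.sheet_angle_rad
        # pick frames/pixels whose sample points fall strictly inside
        r = np.arange(small_geometry.frame_shape[0])
        depth = r * p * math.sin(theta)
        expected = background * np.exp(-depth / 100.0)
        k = stack.n_frames // 2
        interior_rows = depth < ph.thickness_um - ph.voxel_pitch
        interior_cols = slice(1, int(ph.width_um / p) - 1)
        got = stack.frames[k][interior_rows, interior_cols]
        np.testing.assert_allclose(
            got, np.broadcast_to(expected[interior_rows, None], got.shape),
            rtol=1e-10)

    def test_determinism(self, small_geometry):
        ph = generate_phantom(100, 60, 60, {}, 2.0, seed=0)
        noise = NoiseParams(photon_scale=20.0, read_noise_sd=1.0)
        a = simulate_acquisition(ph, small_geometry, noise, seed=9)
        b = simulate_acquisition(ph, small_geometry, noise, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_point_source_matches_brute_force(self, small_geometry, noiseless):
        """Implementation equals the explicit forward-mapping oracle."""
        ph = delta_phantom((24, 24, 24), voxel_pitch=2.0,
                           source_zyx=(10, 12, 14))
        stack = simulate_acquisition(ph, small_geometry, noiseless, seed=0)
        n_check = min(stack.n_frames, 30)
        oracle = brute_force_frames(ph, small_geometry, n_check)
        np.testing.assert_allclose(stack.frames[:n_check], oracle, atol=1e-9)

    def test_point_source_brightest_pixel_inverts_mapping(self, noiseless):
        """Brightest pixel sits where inverting the forward mapping says."""
        # exact-alignment geometry: sample lattice == voxel lattice
        geom = AcquisitionGeometry(native_pixel_pitch=2.0, binning=1,
                                   sheet_angle=45.0,
                                   frame_interval=2.0 * math.cos(math.radians(45)),
                                   roi_rows=16, roi_cols=16)
        v = 2.0 * math.sin(math.radians(45))  # voxel pitch = z sample pitch
        src = (6, 8, 9)  # z, y, x voxel indices
        ph = delta_phantom((16, 20, 20), voxel_pitch=v, source_zyx=src)
        stack = simulate_acquisition(ph, geom, noiseless, seed=0)
        k, r, c = np.unravel_index(np.argmax(stack.frames),
                                   stack.frames.shape)
        p, theta = geom.binned_pitch, geom.sheet_angle_rad
        s = geom.frame_interval_um
        # invert: r* = z0/(p sin), c* = y0/p, k* = (x0 - r* p cos)/s
        z0, y0, x0 = (i * v for i in src)
        r_star = z0 / (p * math.sin(theta))
        c_star = y0 / p
        k_star = (x0 - r_star * p * math.cos(theta)) / s
        assert abs(r - r_star) <= 1
        assert abs(c - c_star) <= 1
        assert abs(k - k_star) <= 1

    def test_frame_width_is_about_900_um(self):
        geom = AcquisitionGeometry()
        width_um = geom.frame_shape[1] * geom.binned_pitch
        assert width_um == pytest.approx(901.12)
        assert round(geom.strip_width_mm, 1) == 0.9

    def test_attenuation_monotonic_in_depth(self, small_geometry):
        """Constant phantom: deeper rows are never brighter."""
        ph = generate_phantom(100, 60, 100, {}, 2.0, seed=0)
        noise = NoiseParams(photon_scale=None, read_noise_sd=0.0,
                            attenuation_length_um=50.0)
        stack = simulate_acquisition(ph, small_geometry, noise, seed=0)
        p = small_geometry.binned_pitch
        theta = small_geometry.sheet_angle_rad
        depth = np.arange(small_geometry.frame_shape[0]) * p * math.sin(theta)
        inside = depth < ph.thickness_um - ph.voxel_pitch
        k = stack.n_frames // 2
        col = stack.frames[k][inside, 4]
        assert np.all(np.diff(col) <= 1e-12)

    def test_photon_conservation_aligned_delta(self):
        """Delta source on an aligned sample lattice: pixel sum == intensity.

        Geometry chosen so each 1D sample lattice forms a partition of
        unity for the interpolation hat: frame interval = voxel pitch,
        z-sample pitch p*sin(30 deg) = voxel pitch, and the source placed
        exactly on a lateral sample column (y lattice pitch 2x voxel).
        """
        geom = AcquisitionGeometry(native_pixel_pitch=2.0, binning=1,
                                   sheet_angle=30.0, frame_interval=1.0,
                                   roi_rows=24, roi_cols=24)
        intensity = 137.0
        # source inside the swept region: x >= z * cot(30 deg) = 1.73 z
        ph = delta_phantom((20, 20, 20), voxel_pitch=1.0,
                           source_zyx=(4, 10, 12), intensity=intensity)
        stack = simulate_acquisition(ph, geom, NOISELESS, seed=0)
        assert stack.frames.sum() == pytest.approx(intensity, rel=1e-12)

    def test_shot_noise_changes_values_and_stays_nonnegative(self,
                                                             small_geometry):
        ph = generate_phantom(100, 60, 60, {}, 2.0, seed=0)
        noisy = NoiseParams(photon_scale=5.0, read_noise_sd=3.0)
        stack = simulate_acquisition(ph, small_geometry, noisy, seed=1)
        clean = simulate_acquisition(ph, small_geometry, NOISELESS, seed=1)
        assert np.all(stack.frames >= 0)
        assert not np.array_equal(stack.frames, clean.frames)

    def test_too_wide_phantom_rejected(self, small_geometry):
        ph = generate_phantom(100, 200, 60, {}, 2.0, seed=0)
        with pytest.raises(ValueError, match="strip"):
            simulate_acquisition(ph, small_geometry, NOISELESS, seed=0)

    def test_nonpositive_attenuation_rejected(self):
        with pytest.raises(ValueError, match="attenuation"):
            NoiseParams(attenuation_length_um=0.0)


class TestSerialization:
    def test_stack_round_trip(self, tmp_path, small_geometry):
        ph = generate_phantom(100, 60, 60, {}, 2.0, seed=0)
        stack = simulate_acquisition(ph, small_geometry, NOISELESS, seed=4)
        save_stack(stack, tmp_path / "stack.tif")
        back = load_stack(tmp_path / "stack.tif")
        np.testing.assert_allclose(back.frames,
                                   stack.frames.astype(np.float32))
        assert back.geometry == small_geometry
        assert back.seed == 4
        assert math.isinf(back.noise_params.attenuation_length_um)

    def test_phantom_round_trip(self, tmp_path):
        ph = generate_phantom(300, 200, 80, {"benign": 1, "gleason3": 1},
                              2.0, seed=2)
        save_phantom(ph, tmp_path / "ph.tif")
        back = load_phantom(tmp_path / "ph.tif")
        np.testing.assert_allclose(back.volume,
                                   ph.volume.astype(np.float32))
        np.testing.assert_array_equal(back.labels, ph.labels)
        assert back.truth_label == "cancer"
        assert back.glands == ph.glands


class TestRawStackInvariants:
    def test_empty_stack_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            RawStack(frames=np.zeros((0, 32, 64)), geometry=small_geometry,
                     noise_params=NOISELESS, seed=0)

    def test_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="does not match"):
            RawStack(frames=np.zeros((3, 8, 8)), geometry=small_geometry,
                     noise_params=NOISELESS, seed=0)

    def test_negative_pixels_rejected(self, small_geometry):
        frames = np.zeros((2, 32, 64))
        frames[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            RawStack(frames=frames, geometry=small_geometry,
                     noise_params=NOISELESS, seed=0)
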