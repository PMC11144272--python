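"""Volume bookkeeping: downsampling, sample construction, interpolation."""

import numpy as np
import pytest

from emrestore import vem
from emrestore.vem import VolumeSpec


def _vol(depth=24, lat=16, voxel=(8.0, 8.0, 8.0), seed=0):
    rng = np.random.default_rng(seed)
    return VolumeSpec(data=rng.random((depth, lat, lat)), voxel_size=voxel)


class TestVolumeSpec:
    def test_R_from_voxel_ratio(self):
        assert VolumeSpec(np.zeros((4, 4, 4)),
                          voxel_size=(48.0, 8.0, 8.0)).R == 5
        assert VolumeSpec(np.zeros((4, 4, 4)),
                          voxel_size=(8.0, 8.0, 8.0)).R == 0

    def test_dim_validation(self):
        with pytest.raises(ValueError):
            VolumeSpec(np.zeros((1, 4, 4)))


class TestDownsampleAxial:
    def test_mod6_voxel_size(self):
        """Mod-6 retention turns an 8 nm axial step into 48 nm."""
        out = vem.downsample_axial(_vol(depth=30), 6)
        assert out.voxel_size == (48.0, 8.0, 8.0)
        assert out.R == 5

    def test_1024_layers_keep_171(self):
        # kept 1-based indices 1, 7, ..., 1021
        out = vem.downsample_axial(_vol(depth=1024), 6)
        assert out.M == 171

    def test_identity_factor(self):
        v = _vol()
        out = vem.downsample_axial(v, 1)
        np.testing.assert_array_equal(out.data, v.data)

    def test_retained_count_matches_brute_force(self):
        """Kept-layer count vs direct enumeration of 1-based indices with
        j mod f == 1, for 100 random (M, f)."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            f = int(rng.integers(1, 12))
            m = int(rng.integers(2 * f + 1, 200 + 2 * f))
            out = vem.downsample_axial(_vol(depth=m), f)
            brute = sum(1 for j in range(1, m + 1) if j % f == 1 % f)
            assert out.M == brute

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            vem.downsample_axial(_vol(), 0)


class TestTrainingSampleConstruction:
    def test_index_arithmetic_i(self):
        """M=13, R=5, anchor u=1: lower layer index 7, targets 2..6
        (1-based), matching c^l = c^(u+R+1)."""
        v = _vol(depth=13)
        samples = vem.build_training_samples_i(v, 5)
        first = samples[0]
        assert first.u == 1
        np.testing.assert_array_equal(first.upper, v.data[0])
        np.testing.assert_array_equal(first.lower, v.data[6])
        assert len(first.targets) == 5
        np.testing.assert_array_equal(first.targets[0], v.data[1])
        np.testing.assert_array_equal(first.targets[4], v.data[5])

    def test_anchor_count_boundary(self):
        # M = R + 2 leaves exactly one valid anchor
        assert len(vem.build_training_samples_i(_vol(depth=7), 5)) == 1
        assert len(vem.build_training_samples_i(_vol(depth=13), 5)) == 7

    def test_r_zero_rejected(self):
        with pytest.raises(ValueError):
            vem.build_training_samples_i(_vol(), 0)

    def test_too_shallow_rejected(self):
        with pytest.raises(ValueError):
            vem.build_training_samples_i(_vol(depth=6), 5)

    def test_axis_a_slices_are_zx_views(self):
        """(Z,Y,X) = (13, 64, 64), R=5: 58 anchors of (Z, X) slices."""
        v = _vol(depth=13, lat=64)
        samples = vem.build_training_samples_a(v, 5)
        assert len(samples) == 58
        assert samples[0].axis == "y"
        assert samples[0].upper.shape == (13, 64)
        np.testing.assert_array_equal(samples[0].upper, v.data[:, 0, :])

    def test_as_diffusion_samples_indexing(self):
        v = _vol(depth=8)
        ds = vem.as_diffusion_samples(vem.build_training_samples_i(v, 2))
        # anchors u=1..5, each with j in {1, 2}
        assert len(ds) == 10
        assert {s.j for s in ds} == {1, 2}
        assert ds[0].cond.shape == (2, 16, 16)


class TestInferIsotropic:
    def test_layer_counts(self, linear_blend_net, toy_schedule):
        net = linear_blend_net(5)
        for m, expected in ((3, 13), (2, 7)):
            v = VolumeSpec(np.random.default_rng(0).random((m, 16, 16)),
                           voxel_size=(48.0, 8.0, 8.0))
            out, _ = vem.infer_isotropic(v, net, toy_schedule, K=1)
            assert out.M == expected
            assert out.voxel_size[0] == pytest.approx(8.0)

    def test_r_zero_identity(self, toy_schedule):
        v = _vol(depth=5, voxel=(8.0, 8.0, 8.0))
        out, reports = vem.infer_isotropic(v, None, toy_schedule)
        np.testing.assert_array_equal(out.data, v.data)
        assert reports == []

    def test_linear_blend_oracle_equals_linear_interp(self, toy_schedule,
                                                      linear_blend_net):
        """An oracle predicting the linear blend of the bounding layers
        reproduces the linear interpolation stack to 1e-5."""
        rng = np.random.default_rng(2)
        R = 3
        v = VolumeSpec(np.clip(rng.random((3, 12, 12)), 0.05, 0.95),
                       voxel_size=(32.0, 8.0, 8.0))
        out, _ = vem.infer_isotropic(v, linear_blend_net(R), toy_schedule,
                                     K=2, seed=0)
        fine = np.linspace(0, v.M - 1, out.M)
        expected = np.stack([
            (1 - (z - int(z))) * v.data[int(z)]
            + (z - int(z)) * v.data[min(int(z) + 1, v.M - 1)]
            for z in fine])
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_inserted_layer_bookkeeping(self, linear_blend_net,
                                        toy_schedule):
        """Output index of input layer c^(u+1) is (u+1)*(R+1), checked
        with marker volumes."""
        R = 4
        marks = np.arange(4, dtype=float)[:, None, None] \
            * np.ones((1, 8, 8)) / 4.0
        v = VolumeSpec(marks, voxel_size=(40.0, 8.0, 8.0))
        out, _ = vem.infer_isotropic(v, linear_blend_net(R), toy_schedule,
                                     K=1)
        for u in range(4):
            np.testing.assert_array_equal(out.data[u * (R + 1)], v.data[u])

    def test_single_layer_rejected(self):
        # a 1-layer stack violates the VolumeSpec invariant outright
        with pytest.raises(ValueError):
            VolumeSpec(np.zeros((1, 8, 8)), voxel_size=(48.0, 8.0, 8.0))


class TestCubicBaseline:
    def test_constant_volume(self):
        v = VolumeSpec(np.full((6, 8, 8), 0.4), voxel_size=(48.0, 8.0, 8.0))
        out = vem.cubic_baseline(v, 6)
        np.testing.assert_allclose(out.data, 0.4, atol=1e-12)
        assert out.M == 31

    def test_linear_profile_exact(self):
        z = np.arange(6, dtype=float)[:, None, None]
        v = VolumeSpec(np.broadcast_to(z / 10.0, (6, 8, 8)).copy(),
                       voxel_size=(48.0, 8.0, 8.0))
        out = vem.cubic_baseline(v, 6)
        fine = np.arange(out.M) / 6.0 / 10.0
        np.testing.assert_allclose(out.data[:, 0, 0], fine, atol=1e-6)

    def test_matches_independent_spline(self):
        """Sine profile along z vs direct scipy CubicSpline evaluation per
        voxel column."""
        from scipy.interpolate import CubicSpline

        rng = np.random.default_rng(3)
        z = np.arange(8, dtype=float)
        prof = np.sin(2 * np.pi * z / 16.0)
        vol = prof[:, None, None] + 0.1 * rng.random((1, 4, 4))
        v = VolumeSpec(vol, voxel_size=(16.0, 8.0, 8.0))
        out = vem.cubic_baseline(v, 2)
        fine = np.arange(out.M) / 2.0
        for y in range(4):
            for x in range(4):
                expected = CubicSpline(z, vol[:, y, x])(fine)
                np.testing.assert_allclose(out.data[:, y, x], expected,
                                           atol=1e-8)

    def test_needs_four_layers(self):
        with pytest.raises(ValueError):
            vem.cubic_baseline(
                VolumeSpec(np.zeros((3, 8, 8)),
                           voxel_size=(48.0, 8.0, 8.0)), 6)
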