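"""Moment projections against brute-force oracles, plus packing."""

import numpy as np
import pytest

from brainage2d import (BrainVolume, ChannelTag, DEFAULT_CHANNELS, load_packed,
                        pack_cohort, project, save_packed)
from brainage2d.projection import PLANE_AXIS, PLANES, canonical_order

ALL_CHANNELS = tuple(ChannelTag(p, s) for p in PLANES
                     for s in ("mean", "std", "skew", "kurtosis"))


def brute_force_projection(data: np.ndarray, plane: str, statistic: str) -> np.ndarray:
    """Per-pixel loop over slices along the reduced axis."""
    axis = PLANE_AXIS[plane]
    moved = np.moveaxis(data, axis, 0).astype(np.float64)
    n, h, w = moved.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            series = moved[:, i, j]
            mu = series.sum() / n
            var = ((series - mu) ** 2).sum() / n
            sd = np.sqrt(var)
            if statistic == "mean":
                out[i, j] = mu
            elif statistic == "std":
                out[i, j] = sd
            elif statistic == "skew":
                out[i, j] = 0.0 if sd == 0 else (((series - mu) ** 3).sum() / n) / sd ** 3
            elif statistic == "kurtosis":
                out[i, j] = 0.0 if sd == 0 else (((series - mu) ** 4).sum() / n) / sd ** 4
    return out


class TestProject:
    def test_constant_volume_closed_form(self):
        vol = BrainVolume(np.full((4, 4, 4), 0.7, np.float32))
        ps = project(vol, DEFAULT_CHANNELS)
        for tag, img in ps.images.items():
            expected = 0.7 if tag.statistic == "mean" else 0.0
            np.testing.assert_allclose(img, expected, atol=1e-7)

    def test_two_point_population_std(self):
        """Values {0, 2} along the reduced axis: mean 1, population std 1."""
        data = np.zeros((2, 2, 2), np.float32)
        data[:, :, 1] = 2.0  # varies along axis 2 = axial reduction
        ps = project(BrainVolume(data), (ChannelTag("axial", "mean"),
                                         ChannelTag("axial", "std")))
        np.testing.assert_allclose(ps.images[ChannelTag("axial", "mean")], 1.0)
        np.testing.assert_allclose(ps.images[ChannelTag("axial", "std")], 1.0)

    @pytest.mark.parametrize("channel", ALL_CHANNELS, ids=str)
    def test_matches_brute_force_oracle(self, channel, rng):
        data = rng.random((16, 16, 12)).astype(np.float32)
        ps = project(BrainVolume(data), (channel,))
        oracle = brute_force_projection(data, channel.plane, channel.statistic)
        np.testing.assert_allclose(ps.images[channel], oracle, rtol=1e-5, atol=1e-6)

    def test_flip_equivariance(self, rng):
        """Flipping along a non-reduced axis flips the projection image."""
        data = rng.random((8, 8, 6)).astype(np.float32)
        base = project(BrainVolume(data), DEFAULT_CHANNELS)
        flipped = project(BrainVolume(data[::-1].copy()), DEFAULT_CHANNELS)
        tag = ChannelTag("axial", "mean")  # axial image axes = (axis0, axis1)
        np.testing.assert_allclose(flipped.images[tag], base.images[tag][::-1],
                                   rtol=1e-6)

    def test_slice_permutation_invariance(self, rng):
        data = rng.random((6, 6, 10)).astype(np.float32)
        perm = rng.permutation(10)
        a = project(BrainVolume(data), DEFAULT_CHANNELS)
        b = project(BrainVolume(data[:, :, perm].copy()), DEFAULT_CHANNELS)
        for tag in (ChannelTag("axial", "mean"), ChannelTag("axial", "std")):
            np.testing.assert_allclose(a.images[tag], b.images[tag], rtol=1e-6)

    def test_mean_conservation(self, rng):
        """mean image x number of slices sums to the volume total."""
        data = rng.random((7, 9, 11)).astype(np.float32)
        ps = project(BrainVolume(data), (ChannelTag("coronal", "mean"),))
        img = ps.images[ChannelTag("coronal", "mean")]
        assert img.sum() * 9 == pytest.approx(data.sum(), rel=1e-5)

    def test_std_nonnegative(self, tiny_cohort):
        ps = project(tiny_cohort.volumes[0], DEFAULT_CHANNELS)
        for tag, img in ps.images.items():
            if tag.statistic in ("std", "kurtosis"):
                assert (img >= 0).all()

    def test_empty_channel_set_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="empty"):
            project(tiny_cohort.volumes[0], ())

    def test_axial_mean_left_right_symmetric_without_jitter(self):
        from brainage2d import PhantomParams, generate_phantom
        p = PhantomParams(grid_shape=(16, 16, 16), shell_thickness_at_44=3.0,
                          thinning_rate=0.05, ventricle_radius_at_44=2.0,
                          subject_variability=0.0, noise_sigma=0.0)
        ps = project(generate_phantom(p, 60, 0), (ChannelTag("axial", "mean"),))
        img = ps.images[ChannelTag("axial", "mean")]
        np.testing.assert_allclose(img, img[::-1], atol=1e-5)


class TestPackedDataset:
    def test_shapes_and_channel_grouping(self, tiny_packed, tiny_cohort):
        n_train = sum(1 for s in tiny_cohort.split if s == "train")
        sp = tiny_packed.splits["train"]
        assert sp.n == n_train
        for plane in PLANES:
            assert sp.planes[plane].shape == (n_train, 2, 16, 16)

    def test_manifest_order_preserved(self, tiny_packed, tiny_cohort):
        want = [sid for sid, lab in zip(tiny_cohort.subject_ids, tiny_cohort.split)
                if lab == "train"]
        assert tiny_packed.splits["train"].subject_ids == want

    def test_save_load_round_trip(self, tiny_packed, tmp_path):
        p = save_packed(tiny_packed, tmp_path / "ds.npz")
        loaded = load_packed(p)
        assert loaded.channels == tiny_packed.channels
        for name, sp in tiny_packed.splits.items():
            np.testing.assert_array_equal(loaded.splits[name].ages, sp.ages)
            for plane, arr in sp.planes.items():
                np.testing.assert_array_equal(loaded.splits[name].planes[plane], arr)

    def test_repack_byte_identical(self, tiny_packed, tmp_path):
        a = save_packed(tiny_packed, tmp_path / "a.npz").read_bytes()
        b = save_packed(tiny_packed, tmp_path / "b.npz").read_bytes()
        assert a == b

    def test_subset_selects_channels(self, tiny_packed):
        sub = tiny_packed.subset((ChannelTag("axial", "std"),))
        assert sub.plane_names == ("axial",)
        sp = tiny_packed.splits["train"]
        np.testing.assert_array_equal(sub.splits["train"].planes["axial"],
                                      sp.planes["axial"][:, 1:2])

    def test_subset_unknown_channel_rejected(self, tiny_packed):
        with pytest.raises(ValueError, match="skew"):
            tiny_packed.subset((ChannelTag("axial", "skew"),))


def test_canonical_order_is_plane_major():
    chans = canonical_order([ChannelTag("sagittal", "std"), ChannelTag("axial", "mean"),
                             ChannelTag("axial", "std")])
    assert [str(c) for c in chans] == ["axial-mean", "axial-std", "sagittal-std"]
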