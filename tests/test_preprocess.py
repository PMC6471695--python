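import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryores import (
    BACKGROUND,
    DensityMap,
    LabeledVolume,
    ResolutionClass3,
    SplitSpec,
    apply_mask,
    bin_resolution10,
    central_crop_or_pad,
    minmax_normalize,
    pad_to_pow2,
    partition_patches,
    reassemble_patches,
    split_dataset,
    three_class_label,
)


class TestNormalization:
    def test_maps_to_unit_range(self):
        dm = DensityMap(np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3))
        out = minmax_normalize(dm)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_constant_map_becomes_zero(self):
        out = minmax_normalize(DensityMap(np.full((3, 3, 3), 7.0)))
        assert np.all(out.data == 0.0)

    def test_range_and_idempotence(self, rng):
        dm = DensityMap(rng.normal(size=(6, 6, 6)))
        once = minmax_normalize(dm)
        assert once.data.min() == pytest.approx(0.0)
        assert once.data.max() == pytest.approx(1.0)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-7)


class TestResolutionLabels:
    @pytest.mark.parametrize(
        "resolution,expected",
        [
            (2.5, ResolutionClass3.HIGH),
            (7.5, ResolutionClass3.MEDIUM),
            (12.5, ResolutionClass3.LOW),
            (5.0, ResolutionClass3.MEDIUM),
            (10.0, ResolutionClass3.MEDIUM),
            (4.999, ResolutionClass3.HIGH),
            (10.001, ResolutionClass3.LOW),
        ],
    )
    def test_three_class_boundaries(self, resolution, expected):
        assert three_class_label(resolution) is expected

    @pytest.mark.parametrize(
        "resolution,expected",
        [(1.999, 0), (2.0, 1), (2.5, 1), (3.0, 2), (9.999, 8), (10.0, 9), (12.5, 9), (100.0, 9)],
    )
    def test_ten_bin_boundaries(self, resolution, expected):
        assert bin_resolution10(resolution) == expected

    def test_binning_is_monotone(self):
        grid = np.linspace(0.1, 30.0, 400)
        bins = bin_resolution10(grid)
        assert np.all(np.diff(bins) >= 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            three_class_label(0.0)
        with pytest.raises(ValueError):
            bin_resolution10(-1.0)

    def test_labeled_volume_pairing(self, small_map, rng):
        assert LabeledVolume(small_map, ResolutionClass3.HIGH).label == 0
        voxel_labels = rng.integers(-1, 10, size=small_map.shape)
        assert LabeledVolume(small_map, voxel_labels).label.shape == small_map.shape
        with pytest.raises(ValueError, match="dimensions"):
            LabeledVolume(small_map, np.zeros((2, 2, 2), dtype=np.int64))
        with pytest.raises(ValueError, match="label values"):
            LabeledVolume(small_map, np.full(small_map.shape, 42))

    def test_three_class_consistent_on_training_resolutions(self):
        # bins 1 and 9 land in the same coarse groups as the 3-way rule
        assert three_class_label(2.5) is ResolutionClass3.HIGH
        assert bin_resolution10(2.5) == 1
        assert three_class_label(12.5) is ResolutionClass3.LOW
        assert bin_resolution10(12.5) == 9


class TestCropPad:
    def test_large_input_center_cropped(self, rng):
        data = rng.random((128, 128, 128), dtype=np.float32)
        out = central_crop_or_pad(DensityMap(data), 64)
        assert out.shape == (64, 64, 64)
        np.testing.assert_array_equal(out.data, data[32:96, 32:96, 32:96])
        np.testing.assert_allclose(out.origin, [32.0, 32.0, 32.0])

    def test_small_input_zero_padded_at_end(self, rng):
        data = rng.random((45, 45, 45), dtype=np.float32)
        out = central_crop_or_pad(DensityMap(data), 64)
        assert out.shape == (64, 64, 64)
        np.testing.assert_array_equal(out.data[:45, :45, :45], data)
        assert np.all(out.data[45:] == 0)
        assert np.all(out.data[:, 45:] == 0)
        assert np.all(out.data[:, :, 45:] == 0)

    def test_exact_size_is_identity(self, rng):
        data = rng.random((64, 64, 64), dtype=np.float32)
        out = central_crop_or_pad(DensityMap(data), 64)
        np.testing.assert_array_equal(out.data, data)

    def test_mixed_axes(self, rng):
        data = rng.random((100, 64, 30), dtype=np.float32)
        out = central_crop_or_pad(DensityMap(data), 64)
        assert out.shape == (64, 64, 64)


class TestMasking:
    def test_all_ones_identity(self, small_map):
        out = apply_mask(small_map, np.ones(small_map.shape, dtype=np.uint8))
        np.testing.assert_array_equal(out.data, small_map.data)

    def test_all_zeros_blanks(self, small_map):
        out = apply_mask(small_map, np.zeros(small_map.shape, dtype=np.uint8))
        assert np.all(out.data == 0)

    def test_half_box(self, small_map):
        mask = np.ones(small_map.shape, dtype=np.uint8)
        mask[6:] = 0
        out = apply_mask(small_map, mask)
        np.testing.assert_array_equal(out.data[:6], small_map.data[:6])
        assert np.all(out.data[6:] == 0)

    def test_shape_mismatch_rejected(self, small_map):
        with pytest.raises(ValueError):
            apply_mask(small_map, np.ones((2, 2, 2)))

    def test_non_binary_rejected(self, small_map):
        with pytest.raises(ValueError):
            apply_mask(small_map, np.full(small_map.shape, 2))


class TestPow2Padding:
    def test_power_of_two_passthrough(self, rng):
        data = rng.random((64, 64, 64), dtype=np.float32)
        out = pad_to_pow2(DensityMap(data), seed=0)
        np.testing.assert_array_equal(out.data, data)

    def test_next_power_of_two(self, rng):
        out = pad_to_pow2(DensityMap(rng.random((100, 100, 100), dtype=np.float32)), seed=0)
        assert out.shape == (128, 128, 128)

    def test_cube_target_from_max_dim(self, rng):
        out = pad_to_pow2(DensityMap(rng.random((20, 40, 70), dtype=np.float32)), seed=0)
        assert out.shape == (128, 128, 128)

    def test_odd_leftover_reproducible(self, rng):
        data = rng.random((45, 45, 45), dtype=np.float32)
        a = pad_to_pow2(DensityMap(data), seed=9)
        b = pad_to_pow2(DensityMap(data), seed=9)
        assert a.shape == (64, 64, 64)
        np.testing.assert_array_equal(a.data, b.data)
        # the 19 pad voxels split 9/10 or 10/9 around the data
        nz = np.nonzero(a.data.sum(axis=(1, 2)))[0]
        assert nz.min() in (9, 10)

    def test_label_padded_in_lockstep(self, rng):
        data = rng.random((45, 45, 45), dtype=np.float32) + 0.1
        labels = np.full((45, 45, 45), 3, dtype=np.int64)
        padded, padded_labels = pad_to_pow2(DensityMap(data), seed=4, label=labels)
        assert padded_labels.shape == padded.shape
        np.testing.assert_array_equal((padded.data > 0), (padded_labels != BACKGROUND))


class TestPartition:
    def test_full_map_gives_64_cubes(self, rng):
        data = rng.random((64, 64, 64), dtype=np.float32) + 0.5
        labels = rng.integers(0, 10, size=(64, 64, 64))
        batch = partition_patches(DensityMap(data), labels, cube=16)
        assert len(batch) == 64
        assert batch.inputs.shape == (64, 16, 16, 16)
        assert batch.labels.shape == (64, 16, 16, 16)

    def test_all_zero_map_gives_no_cubes(self):
        batch = partition_patches(
            DensityMap(np.zeros((32, 32, 32))), np.zeros((32, 32, 32), dtype=int), cube=16
        )
        assert len(batch) == 0

    def test_single_octant_identified(self, rng):
        data = np.zeros((32, 32, 32), dtype=np.float32)
        data[16:, :16, 16:] = rng.random((16, 16, 16)) + 0.1
        labels = np.ones((32, 32, 32), dtype=np.int64)
        batch = partition_patches(DensityMap(data), labels, cube=16)
        assert len(batch) == 1
        np.testing.assert_array_equal(batch.offsets[0], [16, 0, 16])

    def test_round_trip_on_nonempty_cubes(self, rng):
        data = rng.random((32, 32, 32), dtype=np.float32)
        data[:16] = 0.0  # two empty slabs of cubes
        labels = rng.integers(0, 10, size=(32, 32, 32))
        batch = partition_patches(DensityMap(data), labels, cube=16)
        volume = reassemble_patches(batch, batch.labels)
        nonzero = data != 0
        np.testing.assert_array_equal(volume[nonzero], labels[nonzero])
        assert np.all(volume[:16] == BACKGROUND)

    def test_empty_batch_reassembles_to_background(self):
        batch = partition_patches(
            DensityMap(np.zeros((16, 16, 16))), np.zeros((16, 16, 16), dtype=int)
        )
        volume = reassemble_patches(batch, batch.labels)
        assert np.all(volume == BACKGROUND)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_patches(
                DensityMap(rng.random((30, 30, 30))), np.zeros((30, 30, 30), dtype=int)
            )

    def test_offset_collision_rejected(self, rng):
        data = rng.random((32, 32, 32), dtype=np.float32) + 0.1
        labels = np.zeros((32, 32, 32), dtype=np.int64)
        batch = partition_patches(DensityMap(data), labels, cube=16)
        batch.offsets[1] = batch.offsets[0]
        with pytest.raises(ValueError, match="collision"):
            reassemble_patches(batch, batch.labels)


class TestSplit:
    def test_sizes_60_20_20(self):
        tr, va, te = split_dataset(list(range(10)), SplitSpec((0.6, 0.2, 0.2), seed=0))
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_sizes_72_8_20(self):
        tr, va, te = split_dataset(list(range(100)), SplitSpec((0.72, 0.08, 0.20), seed=0))
        assert (len(tr), len(va), len(te)) == (72, 8, 20)

    def test_deterministic(self):
        a = split_dataset(list(range(50)), SplitSpec(seed=11))
        b = split_dataset(list(range(50)), SplitSpec(seed=11))
        assert a == b

    def test_empty_input(self):
        assert split_dataset([], SplitSpec(seed=0)) == ([], [], [])

    @given(
        n=st.integers(0, 300),
        seed=st.integers(0, 2**31 - 1),
        cut=st.tuples(st.floats(0.05, 0.9), st.floats(0.05, 0.9)),
    )
    @settings(max_examples=40, deadline=None)
    def test_disjoint_and_covering(self, n, seed, cut):
        lo, hi = sorted(cut)
        ratios = (lo, hi - lo if hi > lo else 0.0, 1.0 - hi)
        ratios = (ratios[0], ratios[1], 1.0 - ratios[0] - ratios[1])
        ids = list(range(n))
        tr, va, te = split_dataset(ids, SplitSpec(ratios, seed=seed))
        assert sorted(tr + va + te) == ids
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.5, 0.5), seed=0)
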