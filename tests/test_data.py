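"""Phantom generation, pairing, patching, augmentation, splits, and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrisr.data import (
    PairedSample,
    PhantomSpec,
    augment,
    extract_patch_pair,
    generate_phantom,
    hflip_pair,
    make_pair,
    read_image,
    read_manifest,
    read_volume_slices,
    rot90_pair,
    split_dataset,
    write_image,
    write_manifest,
)
from mrisr.degradation import bicubic_downsample
from mrisr.losses import laplacian_response


class TestGeneratePhantom:
    def test_deterministic_per_seed(self):
        spec = PhantomSpec(height=64, width=64, seed=3)
        np.testing.assert_array_equal(generate_phantom(spec), generate_phantom(spec))

    def test_degenerate_spec_is_constant(self):
        spec = PhantomSpec(height=48, width=48, n_shapes=0, noise_sd=0.0)
        img = generate_phantom(spec)
        np.testing.assert_allclose(img, img[0, 0])

    def test_default_spec_has_edges(self):
        img = generate_phantom(PhantomSpec(height=96, width=96, seed=1))
        assert np.abs(laplacian_response(img)).max() > 0

    def test_range_and_shape(self):
        img = generate_phantom(PhantomSpec(height=64, width=80, seed=2))
        assert img.shape == (64, 80)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match=">= 32"):
            PhantomSpec(height=16, width=64)


class TestMakePair:
    def test_bd_constant_phantom(self):
        pair = make_pair(np.full((48, 48), 0.3), "bd", 2)
        np.testing.assert_allclose(pair.lr, 0.3, atol=1e-12)

    def test_td_constant_phantom(self):
        pair = make_pair(np.full((48, 48), 0.3), "td", 2)
        np.testing.assert_allclose(pair.lr, 0.3, atol=1e-12)

    def test_study_dimensions(self):
        hr = generate_phantom(PhantomSpec(seed=0))  # 240 x 240 default
        pair = make_pair(hr, "bd", 2)
        assert pair.hr.shape == (240, 240)
        assert pair.lr.shape == (120, 120)

    def test_dimension_invariant_enforced(self, rng):
        with pytest.raises(ValueError, match="exactly"):
            PairedSample(lr=rng.random((10, 10)), hr=rng.random((21, 20)), mode="bd", scale=2)


class TestExtractPatchPair:
    def test_exact_fit_gives_whole_image(self):
        hr = generate_phantom(PhantomSpec(height=48, width=48, seed=5))
        pair = make_pair(hr, "bd", 2)
        patch = extract_patch_pair(pair, patch=24, seed=0)
        np.testing.assert_array_equal(patch.hr, pair.hr)

    def test_bd_redegrade_oracle_bit_exact(self):
        hr = generate_phantom(PhantomSpec(height=96, width=96, seed=6))
        pair = make_pair(hr, "bd", 2)
        patch = extract_patch_pair(pair, patch=24, seed=11)
        assert patch.lr.shape == (24, 24)
        assert patch.hr.shape == (48, 48)
        assert np.array_equal(bicubic_downsample(patch.hr, 2), patch.lr)

    def test_offset_correspondence_in_td_mode(self):
        hr = generate_phantom(PhantomSpec(height=64, width=64, seed=7))
        pair = make_pair(hr, "td", 2)
        patch = extract_patch_pair(pair, patch=16, seed=3)
        # locate the LR patch inside the LR image and check the HR patch
        # sits at exactly s times that offset
        found = False
        for i in range(pair.lr.shape[0] - 15):
            for j in range(pair.lr.shape[1] - 15):
                if np.array_equal(pair.lr[i : i + 16, j : j + 16], patch.lr):
                    np.testing.assert_array_equal(
                        pair.hr[2 * i : 2 * i + 32, 2 * j : 2 * j + 32], patch.hr
                    )
                    found = True
        assert found

    def test_same_seed_same_patch(self):
        pair = make_pair(generate_phantom(PhantomSpec(height=64, width=64, seed=8)), "bd", 2)
        a = extract_patch_pair(pair, patch=16, seed=21)
        b = extract_patch_pair(pair, patch=16, seed=21)
        np.testing.assert_array_equal(a.lr, b.lr)
        np.testing.assert_array_equal(a.hr, b.hr)

    def test_oversized_patch_rejected(self):
        pair = make_pair(np.full((32, 32), 0.5), "bd", 2)
        with pytest.raises(ValueError, match="patch size"):
            extract_patch_pair(pair, patch=24, seed=0)


class TestAugment:
    @pytest.fixture
    def pair(self):
        hr = generate_phantom(PhantomSpec(height=64, width=64, seed=9))
        return make_pair(hr, "bd", 2)

    def test_flip_is_involution(self, pair):
        twice = hflip_pair(hflip_pair(pair))
        np.testing.assert_array_equal(twice.lr, pair.lr)
        np.testing.assert_array_equal(twice.hr, pair.hr)

    def test_rotation_has_order_four(self, pair):
        out = pair
        for _ in range(4):
            out = rot90_pair(out)
        np.testing.assert_array_equal(out.hr, pair.hr)

    def test_same_seed_same_transform(self, pair):
        a, b = augment(pair, seed=4), augment(pair, seed=4)
        np.testing.assert_array_equal(a.lr, b.lr)

    def test_augmented_bd_pair_stays_consistent(self, pair):
        """Flips/rotations commute with separable symmetric resampling, so
        re-degrading the augmented HR reproduces the augmented LR."""
        for seed in range(6):
            aug = augment(pair, seed=seed)
            np.testing.assert_allclose(
                bicubic_downsample(aug.hr, 2), aug.lr, atol=1e-12
            )


class TestSplitDataset:
    def test_published_fractions_on_ten_items(self):
        train, val, test = split_dataset(list(range(10)), seed=0)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_partition_properties(self):
        items = list(range(23))
        train, val, test = split_dataset(items, seed=5)
        combined = sorted(train + val + test)
        assert combined == items
        assert not (set(train) & set(val)) and not (set(val) & set(test))

    def test_deterministic(self):
        assert split_dataset(list(range(12)), seed=3) == split_dataset(list(range(12)), seed=3)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(list(range(10)), fractions=(0.6, 0.1, 0.2))


class TestImageIO:
    def test_sixteen_bit_round_trip(self, tmp_path, rng):
        img = rng.random((20, 20))
        write_image(tmp_path / "a.png", img, bits=16)
        back = read_image(tmp_path / "a.png")
        assert np.abs(back - img).max() <= 0.5 / (2 ** 16 - 1) + 1e-12

    def test_eight_bit_round_trip(self, tmp_path, rng):
        img = rng.random((10, 10))
        write_image(tmp_path / "b.png", img, bits=8)
        assert np.abs(read_image(tmp_path / "b.png") - img).max() <= 0.5 / 255 + 1e-12

    def test_representable_constant_exact(self, tmp_path):
        img = np.full((8, 8), 128 / 255)
        write_image(tmp_path / "c.png", img, bits=8)
        np.testing.assert_array_equal(read_image(tmp_path / "c.png"), img)

    def test_missing_file_error(self, tmp_path):
        with pytest.raises(ValueError, match="cannot read"):
            read_image(tmp_path / "nope.png")

    def test_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            write_image(tmp_path / "d.png", np.full((8, 8), 1.5))

    def test_volume_slicing(self, tmp_path, rng):
        nib = pytest.importorskip("nibabel")
        vol = rng.random((16, 16, 4))
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), tmp_path / "vol.nii.gz")
        slices = read_volume_slices(tmp_path / "vol.nii.gz")
        assert len(slices) == 4
        assert slices[0].shape == (16, 16)
        assert all(s.min() >= 0 and s.max() <= 1 for s in slices)


def test_manifest_round_trip(tmp_path):
    records = [
        {"id": "a", "split": "train", "path_lr": "lr/a.png", "path_hr": "hr/a.png",
         "mode": "bd", "scale": 2},
        {"id": "b", "split": "test", "path_lr": "lr/b.png", "path_hr": "hr/b.png",
         "mode": "td", "scale": 2},
    ]
    write_manifest(tmp_path / "m.csv", records)
    assert read_manifest(tmp_path / "m.csv") == records


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    h=st.integers(8, 24).map(lambda v: v * 2),
    w=st.integers(8, 24).map(lambda v: v * 2),
    s=st.sampled_from([2, 4]),
    mode=st.sampled_from(["bd", "td"]),
    seed=st.integers(0, 100),
)
def test_pair_dimension_relation(h, w, s, mode, seed):
    """Every generated pair satisfies the exact x-s dimension relation."""
    if h % s or w % s or h // s < 2 or w // s < 2:
        return
    hr = np.random.default_rng(seed).random((h, w))
    pair = make_pair(hr, mode, s)
    assert pair.hr.shape == (pair.lr.shape[0] * s, pair.lr.shape[1] * s)
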