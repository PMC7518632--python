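import numpy as np
import pytest

from metabrand.branding import brand_slice
from metabrand.enhancement import (
    ClaheParams,
    NlMeansParams,
    PreparedVolume,
    VolumeError,
    apply_clahe,
    apply_nlmeans,
    compose_rgb,
    enhance_edited_top,
    enhance_slice,
    load_volume,
    select_slices,
    volume_from_array,
)


class TestVolumePreparation:
    def test_nifti_roundtrip(self, tmp_path):
        import nibabel as nib

        rng = np.random.default_rng(0)
        data = rng.random((224, 224, 192)) * 1000
        path = tmp_path / "scan.nii.gz"
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
        vol = load_volume(path)
        assert vol.depth == 192
        assert vol.slices.dtype == np.uint8
        assert vol.source_format == "NIfTI"
        # min-max scaling reaches the full 8-bit range
        assert vol.slices.min() == 0 and vol.slices.max() == 255

    def test_png_stack(self, tmp_path):
        import imageio.v3 as iio

        rng = np.random.default_rng(1)
        d = tmp_path / "stack"
        d.mkdir()
        for i in range(170):
            iio.imwrite(d / f"slice_{i:03d}.png",
                        rng.integers(0, 256, (224, 224)).astype(np.uint8))
        vol = load_volume(d)
        assert vol.depth == 170

    def test_constant_volume_maps_to_zero(self):
        vol = volume_from_array(np.full((170, 224, 224), 57.0))
        assert vol.slices.max() == 0

    def test_shallow_volume_rejected(self):
        with pytest.raises(VolumeError, match="167"):
            volume_from_array(np.zeros((100, 224, 224)))

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(VolumeError):
            load_volume(tmp_path / "nope.nii.gz")

    def test_resampling_to_224(self):
        vol = volume_from_array(np.random.default_rng(2).random((170, 256, 256)))
        assert vol.slices.shape == (170, 224, 224)


class TestSliceSelection:
    def test_indices(self):
        idx = select_slices(192)
        assert len(idx) == 80
        assert idx[0] == 8
        assert idx[-1] == 166
        assert all(b - a == 2 for a, b in zip(idx, idx[1:]))

    def test_minimum_depth_boundary(self):
        assert len(select_slices(167)) == 80
        with pytest.raises(VolumeError):
            select_slices(166)

    def test_length_independent_of_depth(self):
        assert select_slices(167) == select_slices(500)


class TestClahe:
    def test_constant_image_fixed_point(self):
        img = np.full((224, 224), 128, dtype=np.uint8)
        assert np.array_equal(apply_clahe(img), img)

    def test_low_contrast_ramp_is_stretched(self):
        ramp = np.linspace(100, 130, 224 * 224).reshape(224, 224)
        img = np.rint(ramp).astype(np.uint8)
        out = apply_clahe(img)
        assert int(out.max()) - int(out.min()) >= 200

    def test_deterministic(self, random_slice):
        assert np.array_equal(apply_clahe(random_slice), apply_clahe(random_slice))

    def test_shape_and_dtype_preserved(self, random_slice):
        out = apply_clahe(random_slice)
        assert out.shape == random_slice.shape and out.dtype == np.uint8

    def test_non_2d_rejected(self):
        with pytest.raises(VolumeError):
            apply_clahe(np.zeros((224, 224, 3), dtype=np.uint8))


class TestNlMeans:
    def test_constant_image_fixed_point(self):
        img = np.full((224, 224), 128, dtype=np.uint8)
        assert np.array_equal(apply_nlmeans(img), img)

    def test_reduces_noise_around_constant(self, rng):
        noisy = np.clip(128 + rng.normal(0, 10, (224, 224)), 0, 255).astype(np.uint8)
        out = apply_nlmeans(noisy)
        resid_in = (noisy.astype(float) - 128).std()
        resid_out = (out.astype(float) - 128).std()
        assert resid_out < resid_in

    def test_deterministic(self, random_slice):
        assert np.array_equal(apply_nlmeans(random_slice), apply_nlmeans(random_slice))

    def test_non_2d_rejected(self):
        with pytest.raises(VolumeError):
            apply_nlmeans(np.zeros((10,), dtype=np.uint8))


class TestCompose:
    def test_channel_order(self, random_slice):
        a = random_slice
        b = apply_clahe(a)
        c = apply_nlmeans(a)
        enhanced = compose_rgb(a, b, c)
        assert np.array_equal(enhanced.original, a)
        assert np.array_equal(enhanced.clahe, b)
        assert np.array_equal(enhanced.nlmeans, c)

    def test_identical_channels_allowed(self, random_slice):
        enhanced = compose_rgb(random_slice, random_slice, random_slice)
        assert np.array_equal(enhanced.channels[:, :, 0], enhanced.channels[:, :, 2])

    def test_shape_mismatch_rejected(self, random_slice):
        with pytest.raises(VolumeError):
            compose_rgb(random_slice, random_slice[:100], random_slice)

    def test_png_roundtrip(self, random_slice, tmp_path):
        import imageio.v3 as iio

        enhanced = enhance_slice(random_slice)
        path = tmp_path / "slice.png"
        iio.imwrite(path, enhanced.channels)
        back = iio.imread(path)
        assert np.array_equal(back, enhanced.channels)


class TestEditedTopSplice:
    def test_spliced_enhancement_is_exact(self, random_slice, meta, markers):
        base = enhance_slice(random_slice)
        branded = brand_slice(random_slice, meta, markers).image
        spliced = enhance_edited_top(branded, base, edited_rows=10)
        full = enhance_slice(branded)
        assert np.array_equal(spliced.channels, full.channels)

    def test_rejects_edits_outside_stated_rows(self, random_slice):
        base = enhance_slice(random_slice)
        edited = random_slice.copy()
        edited[100, 100] ^= 255
        with pytest.raises(VolumeError):
            enhance_edited_top(edited, base, edited_rows=10)
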