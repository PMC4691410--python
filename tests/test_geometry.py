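"""Mask geometry: FWHM conversion, slice-wise blurring against a direct
convolution oracle, WM restriction, and regional means."""

import numpy as np
import pytest

from mwfcoupling.geometry import (
    GM,
    WM,
    BlurSpec,
    LabelEntry,
    LabelVolume,
    QuantMap,
    adjacent_wm_mask,
    blur_parcel_2d,
    cortical_regional_mean,
    extract_regional_measures,
    fwhm_to_sigma,
    load_label_volume,
    load_quant_map,
    save_label_volume,
    save_quant_map,
    weighted_regional_mean,
)
from mwfcoupling.phantom import PhantomRegionValues, PhantomSpec, generate_phantom


def direct_blur_oracle(mask, sigma_vox, truncate=4.0):
    """O(N*K) separable 2-D convolution in the (0,1) plane with a unit-sum
    truncated Gaussian kernel — brute-force reference for gaussian_filter."""
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    k /= k.sum()
    out = np.zeros_like(mask, dtype=float)
    nx, ny, nz = mask.shape
    for z in range(nz):
        sl = mask[:, :, z].astype(float)
        tmp = np.zeros_like(sl)
        for i in range(nx):
            for di in range(-radius, radius + 1):
                j = i + di
                if 0 <= j < nx:
                    tmp[i, :] += k[di + radius] * sl[j, :]
        res = np.zeros_like(sl)
        for i in range(ny):
            for di in range(-radius, radius + 1):
                j = i + di
                if 0 <= j < ny:
                    res[:, i] += k[di + radius] * tmp[:, j]
        out[:, :, z] = res
    return out


class TestFwhmToSigma:
    def test_four_mm(self):
        assert fwhm_to_sigma(4.0) == pytest.approx(1.6986436006, abs=1e-9)

    def test_definitional_inverse(self):
        assert fwhm_to_sigma(2.35482) == pytest.approx(1.0, abs=1e-5)

    def test_linearity_and_error(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(2 * fwhm_to_sigma(4.0))
        with pytest.raises(ValueError):
            fwhm_to_sigma(0.0)


class TestBlur:
    def test_matches_direct_convolution_oracle(self, rng):
        mask = (rng.random((14, 12, 5)) < 0.3).astype(float)
        spec = BlurSpec(fwhm_mm=4.0)
        vox = (1.2, 1.2, 1.2)
        got = blur_parcel_2d(mask, spec, vox)
        want = direct_blur_oracle(mask, spec.sigma_mm / 1.2)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_slice_mass_conserved(self, rng):
        # pad generously so truncation/boundary loss is negligible
        mask = np.zeros((40, 40, 3))
        mask[17:23, 16:24, :] = 1.0
        out = blur_parcel_2d(mask, BlurSpec(fwhm_mm=4.0), (1.2, 1.2, 1.2))
        for z in range(3):
            assert out[:, :, z].sum() == pytest.approx(mask[:, :, z].sum(), abs=1e-6)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_impulse_response_is_separable_kernel(self):
        mask = np.zeros((21, 21, 1))
        mask[10, 10, 0] = 1.0
        spec = BlurSpec(fwhm_mm=4.0)
        out = blur_parcel_2d(mask, spec, (1.0, 1.0, 1.0))
        s = spec.sigma_mm
        radius = int(spec.truncation_sigmas * s + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        k /= k.sum()
        expected = np.zeros_like(out)
        expected[10 - radius : 10 + radius + 1, 10 - radius : 10 + radius + 1, 0] = np.outer(k, k)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_vanishing_fwhm_is_identity(self):
        mask = np.zeros((8, 8, 2))
        mask[3:5, 3:5, :] = 1.0
        out = blur_parcel_2d(mask, BlurSpec(fwhm_mm=1e-9), (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out, mask)

    def test_empty_parcel_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = blur_parcel_2d(np.zeros((5, 5, 2)), BlurSpec(), (1.0, 1.0, 1.0))
        assert out.sum() == 0

    def test_shift_equivariance(self):
        spec = BlurSpec(fwhm_mm=4.0)
        mask = np.zeros((30, 30, 2))
        mask[8:11, 9:13, :] = 1.0
        out = blur_parcel_2d(mask, spec, (1.2, 1.2, 1.2))
        shifted = np.roll(mask, (3, 2), axis=(0, 1))
        out_shifted = blur_parcel_2d(shifted, spec, (1.2, 1.2, 1.2))
        np.testing.assert_allclose(np.roll(out, (3, 2), axis=(0, 1)), out_shifted, atol=1e-12)

    def test_alternative_plane(self):
        mask = np.zeros((6, 12, 12))
        mask[:, 5:7, 5:7] = 1.0
        out = blur_parcel_2d(mask, BlurSpec(fwhm_mm=3.0, plane=(1, 2)), (1.0, 1.0, 1.0))
        # axis 0 untouched: all slabs identical
        for i in range(1, 6):
            np.testing.assert_array_equal(out[i], out[0])


class TestAdjacentWmMask:
    def test_support_only_on_wm(self, default_phantom):
        spec, (labels, _, _) = default_phantom
        region = labels.label_table[2].region
        blurred = blur_parcel_2d(labels.parcel_mask(region), BlurSpec(), labels.voxel_size_mm)
        wm_weights = adjacent_wm_mask(blurred, labels, region)
        assert wm_weights.max() > 0
        assert np.all(wm_weights[labels.voxels != 1] == 0)
        # support stays within the truncated kernel's square in-plane reach
        from scipy import ndimage

        radius = int(4 * fwhm_to_sigma(4.0) / 1.2 + 0.5)
        near = ndimage.binary_dilation(
            labels.parcel_mask(region), structure=np.ones((3, 3, 1), bool), iterations=radius
        )
        assert np.all(wm_weights[~near] == 0)

    def test_widening_fwhm_never_shrinks_support(self, default_phantom):
        spec, (labels, _, _) = default_phantom
        region = labels.label_table[2].region
        parcel = labels.parcel_mask(region)
        supports = []
        for fwhm in (2.0, 4.0, 8.0):
            blurred = blur_parcel_2d(parcel, BlurSpec(fwhm_mm=fwhm), labels.voxel_size_mm)
            supports.append(adjacent_wm_mask(blurred, labels, region) > 1e-12)
        assert np.all(supports[0] <= supports[1]) and np.all(supports[1] <= supports[2])

    def test_isolated_parcel_raises(self):
        voxels = np.zeros((12, 12, 3), dtype=int)
        voxels[4:8, 4:8, :] = 2  # GM island, no WM anywhere
        labels = LabelVolume(
            voxels, np.eye(4), {2: LabelEntry("island", "left", GM)}
        )
        blurred = blur_parcel_2d(voxels == 2, BlurSpec(), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="no adjacent WM"):
            adjacent_wm_mask(blurred, labels, "island")


class TestRegionalMeans:
    def test_weighted_mean_constant_field(self, uniform_wm_phantom):
        spec, (labels, mwf, _) = uniform_wm_phantom
        region = labels.label_table[2].region
        blurred = blur_parcel_2d(labels.parcel_mask(region), BlurSpec(), labels.voxel_size_mm)
        weights = adjacent_wm_mask(blurred, labels, region)
        assert weighted_regional_mean(mwf, weights) == pytest.approx(0.12, abs=1e-12)

    def test_uniform_weights_reduce_to_plain_mean(self, rng):
        vals = rng.random((6, 6, 2))
        qmap = QuantMap(vals, np.eye(4))
        weights = np.zeros_like(vals)
        weights[1:4, 2:5, 0] = 1.0
        assert weighted_regional_mean(qmap, weights) == pytest.approx(
            vals[1:4, 2:5, 0].mean()
        )

    def test_weight_rescaling_invariance(self, rng):
        vals = rng.random((5, 5, 3))
        w = rng.random((5, 5, 3))
        qmap = QuantMap(vals, np.eye(4))
        assert weighted_regional_mean(qmap, w) == pytest.approx(
            weighted_regional_mean(qmap, 7.3 * w), rel=1e-12
        )

    def test_zero_weight_errors(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_regional_mean(QuantMap(np.ones((3, 3, 3)), np.eye(4)), np.zeros((3, 3, 3)))

    def test_nearby_wm_dominates_weighted_mean(self):
        # WM value 0.10 adjacent to the target parcel, 0.20 in the sectors
        # beyond kernel reach: brute-force voxel sum pins the answer at 0.10
        spec = PhantomSpec(
            grid_shape=(40, 40, 6),
            n_regions=2,
            margin_voxels=2,
            ribbon_thickness_voxels=2,
            region_values=(
                PhantomRegionValues(mwf_gm=0.05, mwf_wm=0.10),
                PhantomRegionValues(mwf_gm=0.05, mwf_wm=0.20),
            ),
        )
        labels, mwf, _ = generate_phantom(spec)
        blurred = blur_parcel_2d(
            labels.parcel_mask("parcel-00"), BlurSpec(fwhm_mm=2.0), labels.voxel_size_mm
        )
        weights = adjacent_wm_mask(blurred, labels, "parcel-00")
        got = weighted_regional_mean(mwf, weights)
        brute = (weights * mwf.voxels).sum() / weights.sum()
        assert got == pytest.approx(brute, rel=1e-12)
        assert got == pytest.approx(0.10, abs=0.02)

    def test_cortical_mean_constant_and_hand_values(self):
        voxels = np.zeros((4, 4, 1), dtype=int)
        voxels[0, 0, 0] = voxels[0, 1, 0] = 2
        labels = LabelVolume(voxels, np.eye(4), {2: LabelEntry("r", "left", GM)})
        field = np.zeros((4, 4, 1))
        field[0, 0, 0], field[0, 1, 0] = 0.0, 0.2
        mean, sd = cortical_regional_mean(QuantMap(field, np.eye(4)), labels, "r")
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.1)
        field[0, 1, 0] = 0.0
        mean, sd = cortical_regional_mean(QuantMap(field, np.eye(4)), labels, "r")
        assert (mean, sd) == (0.0, 0.0)
        with pytest.raises(ValueError, match="empty"):
            cortical_regional_mean(QuantMap(field, np.eye(4)),
                                   LabelVolume(np.zeros_like(voxels), np.eye(4),
                                               {2: LabelEntry("r", "left", GM)}), "r")

    def test_noiseless_phantom_roundtrip(self, uniform_wm_phantom):
        spec, (labels, mwf, t1) = uniform_wm_phantom
        table = extract_regional_measures(labels, mwf, t1)
        assert len(table) == spec.n_regions
        for k, vals in enumerate(spec.values):
            row = table[table["region"] == f"parcel-{k:02d}"].iloc[0]
            assert row["cortical_mwf"] == pytest.approx(vals.mwf_gm, abs=1e-12)
            assert row["cortical_mwf_sd"] == pytest.approx(0.0, abs=1e-12)
            assert row["adjacent_mwf"] == pytest.approx(0.12, abs=1e-12)
            assert row["adjacent_t1_ms"] == pytest.approx(900.0, abs=1e-9)


def test_nifti_roundtrip(tmp_path, default_phantom):
    _, (labels, mwf, _) = default_phantom
    save_label_volume(labels, tmp_path / "lab.nii.gz", tmp_path / "lab.tsv")
    save_quant_map(mwf, tmp_path / "mwf.nii.gz")
    lab2 = load_label_volume(tmp_path / "lab.nii.gz", tmp_path / "lab.tsv")
    mwf2 = load_quant_map(tmp_path / "mwf.nii.gz")
    np.testing.assert_array_equal(lab2.voxels, labels.voxels)
    np.testing.assert_allclose(mwf2.voxels, mwf.voxels)
    assert lab2.label_table == labels.label_table
    np.testing.assert_allclose(lab2.voxel_size_mm, 1.2)
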