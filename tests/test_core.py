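"""Core containers, resampling, smoothing, EDT flagging, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from embryomorph.core import (
    FWHM_TO_SIGMA,
    ImageGrid,
    LabelInfo,
    LabelMap,
    Volume,
    flag_thin_labels,
    gaussian_smooth_fwhm,
    label_max_edt,
    normalize_intensity,
    resample_volume,
    validate_label_info,
)
from embryomorph.errors import (
    DegenerateDataError,
    GridError,
    MissingLabelError,
    ParameterError,
)
from embryomorph.transforms import IdentityTransform, translation_transform


def brute_force_max_edt(mask: np.ndarray) -> float:
    """Exhaustive nearest-exterior scan: for every label voxel, the distance
    to the closest non-label voxel (the border beyond the array counts as
    exterior via one-voxel padding)."""
    padded = np.pad(mask, 1, constant_values=False)
    inside = np.argwhere(padded)
    outside = np.argwhere(~padded)
    best = -np.inf
    for p in inside:
        d = np.sqrt(((outside - p) ** 2).sum(axis=1).min())
        best = max(best, d)
    return float(best)


class TestImageGrid:
    def test_world_convention(self):
        g = ImageGrid((4, 5, 6), spacing_um=14.0, origin_um=(1.0, 2.0, 3.0))
        np.testing.assert_allclose(g.index_to_world([1, 0, 2]), [15.0, 2.0, 31.0])
        np.testing.assert_allclose(
            g.world_to_index(g.index_to_world([3, 4, 5])), [3, 4, 5]
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"shape": (0, 4, 4)},
            {"shape": (4, 4)},
            {"shape": (4, 4, 4), "spacing_um": 0.0},
            {"shape": (4, 4, 4), "spacing_um": -1.0},
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(GridError):
            ImageGrid(**{"spacing_um": 1.0, **kwargs})

    def test_volume_shape_and_finiteness_enforced(self, grid16):
        with pytest.raises(GridError):
            Volume(grid16, np.zeros((8, 8, 8)))
        bad = np.zeros(grid16.shape)
        bad[0, 0, 0] = np.nan
        with pytest.raises(DegenerateDataError):
            Volume(grid16, bad)

    def test_label_invariants(self, grid16):
        with pytest.raises(GridError):
            LabelMap(grid16, -np.ones(grid16.shape, dtype=np.int32))
        with pytest.raises(ParameterError):
            validate_label_info([LabelInfo(1, "a"), LabelInfo(1, "b")])
        with pytest.raises(ParameterError):
            validate_label_info(
                [
                    LabelInfo(1, "a", is_whole_embryo=True),
                    LabelInfo(2, "b", is_whole_embryo=True),
                ]
            )


class TestResampling:
    def test_identity_is_exact(self, rng, grid16):
        vol = Volume(grid16, rng.normal(size=grid16.shape))
        out = resample_volume(vol, IdentityTransform(), grid16)
        assert np.array_equal(out.data, vol.data)

    def test_integer_shift_nearest(self, rng, grid16):
        vol = Volume(grid16, rng.normal(size=grid16.shape))
        # sampling at x + 2 voxels along Z pulls content 2 slices up
        t = translation_transform((2 * grid16.spacing_um, 0, 0))
        out = resample_volume(vol, t, grid16, interp="nearest")
        np.testing.assert_array_equal(out.data[:-2], vol.data[2:])
        assert np.all(out.data[-2:] == 0.0)  # padding at the vacated face

    def test_half_voxel_shift_is_linear_midpoint(self, grid16):
        data = np.zeros(grid16.shape)
        a, b = 3.0, 7.0
        data[:, :, 5] = a
        data[:, :, 6] = b
        t = translation_transform((0, 0, 0.5 * grid16.spacing_um))
        out = resample_volume(vol := Volume(grid16, data), t, grid16)
        np.testing.assert_allclose(out.data[:, :, 5], (a + b) / 2.0)

    def test_round_trip_bound_on_smooth_input(self, smooth_blob48):
        # T then T⁻¹ with trilinear interpolation: band-limited content
        # reconstructs within a small empirical interpolation-error bound
        shift = (5.0, -3.0, 7.0)
        fwd = translation_transform(shift)
        bwd = translation_transform(tuple(-s for s in shift))
        once = resample_volume(smooth_blob48, fwd, smooth_blob48.grid)
        back = resample_volume(once, bwd, smooth_blob48.grid)
        interior = (slice(2, -2),) * 3
        err = np.abs(back.data[interior] - smooth_blob48.data[interior]).max()
        assert err < 2e-2 * smooth_blob48.data.max()


class TestSmoothing:
    def test_constant_volume_is_fixed_point(self, grid16):
        vol = Volume(grid16, np.full(grid16.shape, 3.25))
        out = gaussian_smooth_fwhm(vol, 100.0)
        np.testing.assert_allclose(out.data, 3.25)

    def test_impulse_response_fwhm_is_100um(self):
        grid = ImageGrid((41, 41, 41), spacing_um=14.0)
        data = np.zeros(grid.shape)
        data[20, 20, 20] = 1.0
        out = gaussian_smooth_fwhm(Volume(grid, data), 100.0)
        profile = out.data[20, 20, :]
        half = profile.max() / 2.0
        above = np.where(profile >= half)[0]
        # linear interpolation of the half-maximum crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
        f_hi = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        fwhm_um = (f_hi - f_lo) * grid.spacing_um
        assert abs(fwhm_um - 100.0) <= grid.spacing_um

    def test_impulse_mass_conserved(self):
        grid = ImageGrid((33, 33, 33), spacing_um=14.0)
        data = np.zeros(grid.shape)
        data[16, 16, 16] = 1.0
        out = gaussian_smooth_fwhm(Volume(grid, data), 100.0)
        assert abs(out.data.sum() - 1.0) < 1e-9

    def test_commutes_with_axis_permutation(self, rng):
        grid = ImageGrid((20, 20, 20), spacing_um=14.0)
        vol = Volume(grid, rng.normal(size=grid.shape))
        out = gaussian_smooth_fwhm(vol, 80.0)
        perm = gaussian_smooth_fwhm(Volume(grid, vol.data.transpose(1, 2, 0)), 80.0)
        np.testing.assert_allclose(out.data.transpose(1, 2, 0), perm.data, atol=1e-12)

    def test_bad_fwhm_rejected(self, grid16):
        vol = Volume(grid16, np.zeros(grid16.shape))
        with pytest.raises(ParameterError):
            gaussian_smooth_fwhm(vol, 0.0)


class TestLabelEdt:
    def _label_map(self, masks: dict[int, np.ndarray], shape=(16, 16, 16)):
        data = np.zeros(shape, dtype=np.int32)
        for lab, m in masks.items():
            data[m] = lab
        return LabelMap(ImageGrid(shape), data)

    def test_slab_sphere_and_point(self):
        shape = (24, 24, 24)
        slab = np.zeros(shape, dtype=bool)
        slab[4, 2:10, 2:10] = True  # 1-voxel-thick slab
        z, y, x = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        sphere = (z - 14.0) ** 2 + (y - 12.0) ** 2 + (x - 12.0) ** 2 <= 5.0**2
        point = np.zeros(shape, dtype=bool)
        point[1, 20, 20] = True
        lm = self._label_map({1: slab, 2: sphere, 3: point}, shape)
        assert label_max_edt(lm, 1) == 1.0
        assert abs(label_max_edt(lm, 2) - 5.0) <= 1.0
        assert label_max_edt(lm, 3) == 1.0
        # each equals the exhaustive nearest-exterior scan
        for lab, m in {1: slab, 2: sphere, 3: point}.items():
            assert label_max_edt(lm, lab) == pytest.approx(brute_force_max_edt(m))

    def test_missing_label_raises(self, grid16):
        lm = LabelMap(grid16, np.zeros(grid16.shape, dtype=np.int32))
        with pytest.raises(MissingLabelError):
            label_max_edt(lm, 5)

    def test_flagging_is_strict_and_monotone(self):
        shape = (20, 20, 20)
        slab = np.zeros(shape, dtype=bool)
        slab[3, 2:12, 2:12] = True  # max EDT 1.0
        plus = np.zeros(shape, dtype=bool)  # 3D plus: max EDT sqrt(2)
        plus[10, 10, 10] = True
        for d, s in [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]:
            idx = [10, 10, 10]
            idx[d] += s
            plus[tuple(idx)] = True
        z, y, x = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        sphere = (z - 10.0) ** 2 + (y - 5.0) ** 2 + (x - 5.0) ** 2 <= 4.0**2
        data = np.zeros(shape, dtype=np.int32)
        data[sphere] = 3
        data[slab] = 1
        data[plus] = 2
        lm = LabelMap(ImageGrid(shape), data)
        assert flag_thin_labels(lm, 1.5) == {1, 2}
        # strict '<': a label sitting exactly at the cutoff is retained
        assert flag_thin_labels(lm, np.sqrt(2.0)) == {1}
        # monotone non-decreasing in the cutoff
        flagged = [flag_thin_labels(lm, c) for c in (0.5, 1.0 + 1e-9, 1.5, 10.0)]
        for a, b in zip(flagged, flagged[1:]):
            assert a <= b
        empty = LabelMap(ImageGrid(shape), np.zeros(shape, dtype=np.int32))
        assert flag_thin_labels(empty, 1.5) == set()

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_edt_matches_exhaustive_scan_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 9, 9)
        mask = ndimage.binary_dilation(rng.random(shape) > 0.93)
        if not mask.any():
            mask[4, 4, 4] = True
        lm = LabelMap(ImageGrid(shape), mask.astype(np.int32))
        assert label_max_edt(lm, 1) == pytest.approx(brute_force_max_edt(mask))


class TestNormalizeIntensity:
    def test_affine_invariance_and_idempotence(self, rng, grid16):
        vol = Volume(grid16, rng.normal(size=grid16.shape))
        a = normalize_intensity(vol)
        b = normalize_intensity(Volume(grid16, 3.0 * vol.data + 7.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)
        again = normalize_intensity(a)
        np.testing.assert_allclose(again.data, a.data, atol=1e-10)

    def test_matches_closed_form_on_block(self):
        grid = ImageGrid((3, 3, 3))
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        out = normalize_intensity(Volume(grid, data))
        expect = (data - data.mean()) / data.std()
        np.testing.assert_allclose(out.data, expect, atol=1e-12)
        assert abs(out.data.mean()) < 1e-12 and abs(out.data.std() - 1) < 1e-12

    def test_masked_stats(self, grid16):
        data = np.zeros(grid16.shape)
        data[:8] = np.arange(8 * 16 * 16, dtype=float).reshape(8, 16, 16)
        mask = np.zeros(grid16.shape, dtype=np.int32)
        mask[:8] = 1
        out = normalize_intensity(Volume(grid16, data), LabelMap(grid16, mask))
        sel = out.data[mask > 0]
        assert abs(sel.mean()) < 1e-12 and abs(sel.std() - 1.0) < 1e-12

    def test_zero_variance_rejected(self, grid16):
        with pytest.raises(DegenerateDataError):
            normalize_intensity(Volume(grid16, np.full(grid16.shape, 2.0)))


def test_fwhm_sigma_constant():
    assert FWHM_TO_SIGMA == pytest.approx(1.0 / 2.3548200450309493)
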