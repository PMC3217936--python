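import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.stats import spearmanr

from gwseg.evaluation import dice_coefficient
from gwseg.feature_field import (
    StructuringPlane,
    build_feature_field,
    combine_feature_field,
    directional_tophat,
    mean_curvature_isointensity,
    normalize_linear,
    normalize_sigmoid,
    tophat_gm,
    tophat_wm,
)
from gwseg.phantom import PhantomSpec, make_phantom, multiplicative_bias_field
from gwseg.volume_io import BrainMask, IntensityVolume


class TestStructuringPlane:
    def test_nine_orientations_distinct(self):
        normals = [StructuringPlane(i, 4.0).normal for i in range(9)]
        for i in range(9):
            for j in range(i + 1, 9):
                assert abs(abs(normals[i] @ normals[j])) < 0.999

    @pytest.mark.parametrize("ori", range(9))
    def test_footprint_symmetric(self, ori):
        offs = StructuringPlane(ori, 4.0).footprint_offsets((1.0, 1.0, 1.0))
        as_set = {tuple(o) for o in offs}
        assert {tuple(-o) for o in offs} == as_set

    def test_invalid_orientation(self):
        with pytest.raises(ValueError):
            StructuringPlane(9, 4.0)


class TestDirectionalTophat:
    def test_constant_volume_zero(self):
        vol = IntensityVolume(np.full((16, 16, 16), 50.0))
        for pol in ("dark", "bright"):
            th = directional_tophat(vol, StructuringPlane(0, 4.0), pol)
            np.testing.assert_allclose(th, 0.0, atol=1e-12)

    def test_slab_response_equals_contrast(self):
        """A 3 mm dark slab probed with 4 mm squares responds with the full
        WM-GM contrast away from the volume edges."""
        data = np.full((24, 24, 24), 160.0)
        data[:, :, 11:14] = 90.0  # dark slab, 3 voxels thick
        vol = IntensityVolume(data)
        best = np.zeros_like(data)
        for ori in range(9):
            np.maximum(best, directional_tophat(vol, StructuringPlane(ori, 4.0), "dark"),
                       out=best)
        core = best[8:16, 8:16, 11:14]
        np.testing.assert_allclose(core, 70.0, atol=1e-9)

    def test_thick_slab_no_response(self):
        """Dark structure thicker than every element side is left untouched."""
        data = np.full((40, 40, 40), 160.0)
        data[:, :, 10:28] = 90.0  # 18 mm slab > 14 mm largest element
        vol = IntensityVolume(data)
        for ori in range(9):
            th = directional_tophat(vol, StructuringPlane(ori, 14.0), "dark")
            assert th[20, 20, 19] == pytest.approx(0.0, abs=1e-9)

    def test_oversized_element_rejected(self):
        vol = IntensityVolume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="larger"):
            directional_tophat(vol, StructuringPlane(0, 30.0), "dark")

    def test_nonnegative_on_random_input(self):
        rng = np.random.default_rng(0)
        vol = IntensityVolume(rng.normal(0, 1, (12, 12, 12)))
        for pol in ("dark", "bright"):
            th = directional_tophat(vol, StructuringPlane(4, 4.0), pol)
            assert th.min() >= -1e-9

    def test_duality_of_opening_and_closing(self):
        """Bright top hat of -I equals dark top hat of I (grey-scale duality)."""
        rng = np.random.default_rng(1)
        data = rng.integers(0, 200, (14, 14, 14)).astype(float)
        vol = IntensityVolume(data)
        neg = IntensityVolume(-data)
        for ori in (0, 3, 7):
            el = StructuringPlane(ori, 4.0)
            dark = directional_tophat(vol, el, "dark")
            bright_of_neg = directional_tophat(neg, el, "bright")
            np.testing.assert_allclose(dark, bright_of_neg, atol=1e-9)

    def test_line_and_sheet_detection(self):
        """Both a 1-voxel dark line and a 3 mm dark sheet respond; the sheet
        response is sustained across its footprint."""
        data = np.full((16, 16, 16), 160.0)
        data[8, 8, :] = 90.0  # vessel-like line along z
        line_vol = IntensityVolume(data)
        best = np.zeros_like(data)
        for ori in range(9):
            np.maximum(best, directional_tophat(line_vol, StructuringPlane(ori, 4.0),
                                                "dark"), out=best)
        assert best[8, 8, 8] > 35.0
        sheet = np.full((16, 16, 16), 160.0)
        sheet[:, :, 7:10] = 90.0
        best_s = np.zeros_like(sheet)
        for ori in range(9):
            np.maximum(best_s, directional_tophat(IntensityVolume(sheet),
                                                  StructuringPlane(ori, 4.0), "dark"),
                       out=best_s)
        assert (best_s[4:12, 4:12, 8] > 60.0).all()


class TestMultiscaleTophats:
    def test_constant_volume_zero(self):
        vol = IntensityVolume(np.full((20, 20, 20), 80.0))
        assert np.allclose(tophat_gm(vol), 0.0)
        assert np.allclose(tophat_wm(vol), 0.0)

    def test_phantom_label_statistics(self, dev_truth):
        vol, mask = dev_truth.volume, dev_truth.brain_mask
        wm = dev_truth.wm_mask.data
        gm = mask.data & ~wm
        deep = ndimage.distance_transform_edt(wm) > 4
        thg = tophat_gm(vol, mask)
        assert thg[gm].mean() > thg[deep].mean() + dev_truth.spec.noise_sd
        thw = tophat_wm(vol, mask)
        near = wm & ~deep
        assert thw[near].mean() > thw[gm].mean()


class TestMeanCurvature:
    def test_linear_ramp_zero(self):
        x = np.arange(24, dtype=float)
        vol = IntensityVolume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy())
        mc = mean_curvature_isointensity(vol, presmooth_sd=0.0)
        np.testing.assert_allclose(mc, 0.0, atol=1e-9)

    def test_radial_field_curvature(self):
        """|H| = 1/r for spherical level sets; the rectified response is
        positive on the bright side (WM convention)."""
        n = 48
        c = (n - 1) / 2
        g = np.indices((n, n, n), dtype=float)
        r = np.sqrt(((g - c) ** 2).sum(axis=0))
        vol = IntensityVolume(30.0 - r)
        mc = mean_curvature_isointensity(vol, presmooth_sd=0.0, clip_percentile=100.0)
        for radius in (6.0, 10.0, 16.0):
            shell = (r > radius - 0.5) & (r < radius + 0.5)
            np.testing.assert_allclose(mc[shell].mean(), 1.0 / radius, rtol=0.10)

    def test_negative_presmooth_rejected(self):
        vol = IntensityVolume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError):
            mean_curvature_isointensity(vol, presmooth_sd=-1.0)

    def test_phantom_crests_carry_top_mc(self):
        """Gyral crest voxels (sheet maxima) sit in the top decile of MC^WM."""
        spec = PhantomSpec(shape=(48, 48, 48), fold_amplitude=4.0,
                           fold_wavelength=16.0, noise_sd=2.0, seed=1)
        truth = make_phantom(spec)
        mc = mean_curvature_isointensity(truth.volume, truth.brain_mask)
        lam = spec.fold_wavelength
        x = np.arange(spec.shape[0])[:, None, None] * spec.spacing[0]
        y = np.arange(spec.shape[1])[None, :, None] * spec.spacing[1]
        sheet = np.sin(2 * np.pi * x / lam) * np.sin(2 * np.pi * y / lam)
        z0 = 0.5 * spec.shape[2] * spec.spacing[2]
        z = np.arange(spec.shape[2])[None, None, :] * spec.spacing[2]
        crest = (np.broadcast_to(sheet, spec.shape) > 0.95) & \
            (np.abs(z - (z0 + spec.fold_amplitude * sheet)) < 1.5) & truth.wm_mask.data
        wm = truth.wm_mask.data
        thresh = np.percentile(mc[wm], 90)
        assert mc[crest].mean() > thresh


class TestNormalization:
    def test_sigmoid_midpoint(self):
        f = np.array([[[0.0, 1.0, 2.0, 3.0, 4.0]]])
        out = normalize_sigmoid(f, center=2.0, slope=1.0)
        # midpoint maps to 0.5 before rescaling; after min-max rescale the
        # ordering and symmetry around the center are preserved
        assert out[0, 0, 2] == pytest.approx(0.5, abs=1e-6)

    def test_sigmoid_monotone(self):
        rng = np.random.default_rng(2)
        f = rng.normal(0, 1, (8, 8, 8))
        out = normalize_sigmoid(f, center=0.0, slope=0.5)
        a, b = f.ravel(), out.ravel()
        order = np.argsort(a)
        assert (np.diff(b[order]) >= -1e-12).all()

    @given(
        vals=st.lists(st.floats(-100, 100), min_size=8, max_size=48),
        center=st.floats(-10, 10),
        slope=st.floats(0.05, 20),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_sigmoid_monotone_property(self, vals, center, slope):
        f = np.asarray(vals).reshape(-1, 1, 1)
        out = normalize_sigmoid(f, center=center, slope=slope)
        order = np.argsort(f.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order]) >= -1e-12).all()

    def test_sigmoid_large_slope_approaches_linear(self):
        rng = np.random.default_rng(3)
        f = rng.normal(10, 3, (10, 10, 10))
        sig = normalize_sigmoid(f, center=float(f.mean()), slope=1e5)
        lin = normalize_linear(f)
        assert np.abs(sig - lin).max() < 1e-3

    def test_sigmoid_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            normalize_sigmoid(np.ones((8, 8, 8)), center=0.0, slope=0.0)

    def test_linear_affine_map(self):
        f = np.zeros((1, 1, 3))
        f[0, 0] = [0.0, 5.0, 10.0]
        np.testing.assert_allclose(normalize_linear(f)[0, 0], [0.0, 0.5, 1.0])

    def test_linear_affine_invariance(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, (9, 9, 9))
        np.testing.assert_allclose(normalize_linear(f), normalize_linear(3.7 * f - 11.0),
                                   atol=1e-12)

    def test_linear_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_linear(np.full((8, 8, 8), 2.5))


class TestCombination:
    def test_degenerate_all_zero_rejected(self):
        z = np.zeros((10, 10, 10))
        with pytest.raises(ValueError, match="degenerate"):
            combine_feature_field(z, z, z, np.ones((10, 10, 10), bool))

    def test_empty_mask_rejected(self):
        z = np.zeros((10, 10, 10))
        with pytest.raises(ValueError, match="empty"):
            combine_feature_field(z, z, z, np.zeros((10, 10, 10), bool))

    def test_threshold_signs_and_label_separation(self, dev_truth):
        field = build_feature_field(dev_truth.volume, dev_truth.brain_mask)
        assert field.f_gm < 0 < field.f_wm
        wm = dev_truth.wm_mask.data
        gm = dev_truth.brain_mask.data & ~wm
        assert field.data[wm].mean() > 0 > field.data[gm].mean()

    def test_zero_outside_mask(self, dev_truth):
        field = build_feature_field(dev_truth.volume, dev_truth.brain_mask)
        assert np.all(field.data[~dev_truth.brain_mask.data] == 0)


class TestFieldInvariants:
    def test_separability_thresholding_beats_075(self, dev_truth, young_run,
                                                 young_truth, old_run, old_truth):
        """Thresholding f at 0 already separates WM from cortex (Dice > 0.75)."""
        field_dev = build_feature_field(dev_truth.volume, dev_truth.brain_mask)
        cases = [
            (field_dev, dev_truth),
            (young_run[0].field, young_truth),
            (old_run.field, old_truth),
        ]
        for field, truth in cases:
            d = dice_coefficient((field.data > 0) & truth.brain_mask.data, truth.wm_mask)
            assert d > 0.75

    def test_bias_insensitivity_rank_correlation(self):
        spec = PhantomSpec(shape=(64, 64, 64), bias_strength=0.0, seed=9)
        truth = make_phantom(spec)
        bias = multiplicative_bias_field(spec.shape, spec.spacing, 0.2)
        f1 = build_feature_field(truth.volume, truth.brain_mask).data
        biased = IntensityVolume(truth.volume.data * bias, spacing=spec.spacing)
        f2 = build_feature_field(biased, truth.brain_mask).data
        m = truth.brain_mask.data
        rho = spearmanr(f1[m][::5], f2[m][::5]).statistic
        assert rho > 0.95

    def test_rotation_covariance_of_gm_tophat(self):
        """Rotating a flat slab by 45 degrees changes the mean ribbon response
        by < 25% (the 9-orientation maximum approximates isotropy)."""
        spec = PhantomSpec(shape=(64, 64, 64), fold_amplitude=0.0, noise_sd=4.0,
                           bias_strength=0.0, seed=7)
        truth = make_phantom(spec)
        gm = truth.brain_mask.data & ~truth.wm_mask.data
        gm &= ndimage.distance_transform_edt(~truth.wm_mask.data) <= 3
        core = np.zeros_like(gm)
        core[16:48, 16:48, 16:48] = True
        th0 = tophat_gm(truth.volume, truth.brain_mask)
        m0 = th0[gm & core].mean()
        rot = lambda a, order: ndimage.rotate(a, 45, axes=(0, 2), reshape=False,
                                              order=order, mode="nearest")
        vol_r = IntensityVolume(rot(truth.volume.data, 1), spacing=spec.spacing)
        mask_r = BrainMask(rot(truth.brain_mask.data.astype(float), 0) > 0.5,
                           spacing=spec.spacing)
        gm_r = rot(gm.astype(float), 0) > 0.5
        th1 = tophat_gm(vol_r, mask_r)
        m1 = th1[gm_r & core].mean()
        assert abs(m1 - m0) / m0 < 0.25
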