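"""Distance fields, profiles, region systems, alignment and difference maps."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from tensiongrad import flim, spatial, synthgen as sg
from tensiongrad.flim import LifetimeImage
from tensiongrad.spatial import DistanceField


def brute_force_signed_distance(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    bb = np.argwhere(boundary)
    out = np.empty(mask.shape)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d = np.sqrt(((bb - [r, c]) ** 2).sum(axis=1)).min() * pixel_size
            out[r, c] = -d if mask[r, c] else d
    return out


def flat_image(mask, tau=4.5, photons=10, pixel_size=0.25):
    return LifetimeImage(tau=np.where(mask, float(tau), np.nan),
                         photons=np.asarray(mask, int) * photons, pixel_size=pixel_size)


class TestSignedDistance:
    def test_boundary_pixels_are_zero(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        f = spatial.signed_distance(mask, 1.0)
        boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
        assert np.all(f.d[boundary] == 0)

    def test_monotone_outside(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        f = spatial.signed_distance(mask, 0.5)
        assert f.d[10, 14] > 0
        assert f.d[10, 17] > f.d[10, 14]
        assert f.d[10, 10] < 0

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            spatial.signed_distance(np.zeros((5, 5), bool), 1.0)
        with pytest.raises(ValueError):
            spatial.signed_distance(np.ones((5, 5), bool), 1.0)

    @given(mask=hnp.arrays(bool, (12, 12), elements=st.booleans()))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_bruteforce_on_small_masks(self, mask):
        if not mask.any() or mask.all():
            return
        f = spatial.signed_distance(mask, 0.7)
        assert np.allclose(f.d, brute_force_signed_distance(mask, 0.7))


class TestDecayProfileAndSlope:
    def test_constant_field_flat_profile_zero_sd(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        img = flat_image(mask)
        fld = spatial.inward_distance(mask, 0.25)
        prof = spatial.decay_profile(img, fld, 1.0)
        ok = np.isfinite(prof.mean_tau)
        assert np.allclose(prof.mean_tau[ok], 4.5)
        assert np.allclose(prof.sd_tau[ok], 0.0, atol=1e-9)

    def test_linear_field_bin_means_on_the_line(self):
        mask = np.zeros((60, 60), bool)
        mask[2:58, 2:58] = True
        fld = spatial.inward_distance(mask, 1.0)
        tau = np.where(mask, 4.0 + 0.05 * fld.d, np.nan)
        img = LifetimeImage(tau=tau, photons=np.asarray(mask, int) * 10, pixel_size=1.0)
        prof = spatial.decay_profile(img, fld, 1.0, fit_range=(0, 20))
        ok = np.isfinite(prof.mean_tau)
        # bin means lie on the line within half-bin discretization
        assert np.all(np.abs(prof.mean_tau[ok] - (4.0 + 0.05 * prof.bin_centers[ok])) <= 0.05 / 2 + 1e-12)
        fit = spatial.fit_slope(prof)
        assert fit.slope == pytest.approx(0.05, rel=0.05)
        assert fit.r2 > 0.99

    def test_empty_bins_are_invalid(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        img = flat_image(mask)
        fld = spatial.inward_distance(mask, 0.25)
        prof = spatial.decay_profile(img, fld, 1.0, fit_range=(0, 10))
        assert np.isnan(prof.mean_tau[-1])  # a 10x10 px cell is < 10 um deep

    def test_exact_line_exact_slope(self):
        prof = spatial.GradientProfile(
            bin_centers=np.arange(10) + 0.5, mean_tau=4.0 + 0.02 * (np.arange(10) + 0.5),
            sd_tau=np.zeros(10), n_pixels=np.full(10, 50), n_photons=np.full(10, 1500.0),
            bin_width=1.0)
        fit = spatial.fit_slope(prof)
        assert fit.slope == pytest.approx(0.02, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_profile_zero_slope(self):
        prof = spatial.GradientProfile(
            bin_centers=np.arange(8) + 0.5, mean_tau=np.full(8, 4.4), sd_tau=np.zeros(8),
            n_pixels=np.full(8, 40), n_photons=np.full(8, 1200.0), bin_width=1.0)
        assert spatial.fit_slope(prof).slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        prof = spatial.GradientProfile(
            bin_centers=np.array([0.5, 1.5]), mean_tau=np.array([4.0, 4.1]),
            sd_tau=np.zeros(2), n_pixels=np.array([5, 5]), n_photons=np.array([150.0, 150.0]),
            bin_width=1.0)
        with pytest.raises(ValueError):
            spatial.fit_slope(prof)


class TestFrontRearRegions:
    def test_fraction_counts_on_a_strip(self):
        mask = np.zeros((10, 12), bool)
        mask[:, 1:11] = True  # 100 px strip
        d = np.broadcast_to(np.arange(12, dtype=float), (10, 12)).copy()
        fld = DistanceField(d=d, signed=False)
        regs = spatial.front_rear_by_fraction(mask, fld, 0.2)
        assert regs["front"].sum() == 20
        assert regs["rear"].sum() == 20
        assert not (regs["front"] & regs["rear"]).any()

    def test_half_fraction_partitions_with_ties_to_front(self):
        mask = np.ones((4, 10), bool)
        d = np.broadcast_to(np.arange(10, dtype=float), (4, 10)).copy()
        regs = spatial.front_rear_by_fraction(mask, DistanceField(d=d, signed=False), 0.5)
        assert (regs["front"] | regs["rear"]).all()
        assert not (regs["front"] & regs["rear"]).any()

    def test_ordering_on_linear_field(self):
        mask = np.zeros((30, 60), bool)
        mask[5:25, 5:55] = True
        d = np.broadcast_to(np.arange(60, dtype=float), (30, 60)).copy()
        fld = DistanceField(d=d, signed=False)
        regs = spatial.front_rear_by_fraction(mask, fld, 0.2)
        tau = np.where(mask, 5.0 - 0.01 * d, np.nan)  # higher toward the front
        img = LifetimeImage(tau=tau, photons=np.asarray(mask, int) * 10, pixel_size=1.0)
        assert flim.weighted_mean(img, regs["front"]) > flim.weighted_mean(img, regs["rear"])

    def test_angular_sectors_mirror_symmetric_on_disc(self):
        yy, xx = np.mgrid[:160, :160]
        mask = (xx - 80) ** 2 + (yy - 80) ** 2 <= 60**2
        regs = spatial.front_rear_angular(mask, 0.25, polarity_angle=0.0)
        a_front, a_rear = regs["front"].sum(), regs["rear"].sum()
        assert abs(a_front - a_rear) / a_front < 0.02

    def test_angular_full_depth_covers_sixth_of_disc(self):
        yy, xx = np.mgrid[:160, :160]
        mask = (xx - 80) ** 2 + (yy - 80) ** 2 <= 60**2
        regs = spatial.front_rear_angular(mask, 0.25, 0.0, dmax=np.inf)
        assert regs["front"].sum() / mask.sum() == pytest.approx(60 / 360, rel=0.03)

    def test_polarity_rotation_by_180_swaps_regions(self):
        yy, xx = np.mgrid[:120, :120]
        mask = (xx - 60) ** 2 + (yy - 60) ** 2 <= 45**2
        a = spatial.front_rear_angular(mask, 0.25, 30.0)
        b = spatial.front_rear_angular(mask, 0.25, 210.0)
        assert np.array_equal(a["front"], b["rear"])
        assert np.array_equal(a["rear"], b["front"])


class TestHist2d:
    @pytest.fixture()
    def scene_image(self, cross_scene, cfg, irf):
        stack = sg.simulate_tcspc_image(cross_scene, cfg, seed=0)
        return flim.mask_low_counts(flim.lifetime_image(stack, irf), 20)

    def test_constant_field_constant_cells(self):
        mask = np.zeros((50, 50), bool)
        mask[5:45, 5:45] = True
        img = flat_image(mask)
        fa = spatial.inward_distance(mask, 0.25)
        fb = DistanceField(d=np.broadcast_to(np.arange(50.0), (50, 50)).copy(), signed=False)
        mean, cnt, pho, _ = spatial.hist2d_mean(img, fa, fb, np.arange(0, 6.0), np.arange(0, 50, 5.0))
        assert np.allclose(mean[np.isfinite(mean)], 4.5)

    def test_separable_field_constant_along_other_axis(self):
        mask = np.zeros((50, 50), bool)
        mask[5:45, 5:45] = True
        fa = spatial.inward_distance(mask, 1.0)
        fb = DistanceField(d=np.broadcast_to(np.arange(50.0), (50, 50)).copy(), signed=False)
        tau = np.where(mask, 4.0 + 0.1 * fa.d, np.nan)
        img = LifetimeImage(tau=tau, photons=np.asarray(mask, int) * 7, pixel_size=1.0)
        mean, _, _, _ = spatial.hist2d_mean(img, fa, fb, np.arange(0, 11.0), np.arange(0, 51, 10.0))
        for row in mean:
            ok = np.isfinite(row)
            if ok.sum() > 1:
                assert np.ptp(row[ok]) < 1e-9

    def test_counts_conserve_valid_pixels(self, scene_image, cross_scene):
        fa = spatial.signed_distance(cross_scene.pattern_mask, 0.25, "pattern_boundary")
        fb = spatial.inward_distance(cross_scene.cell_mask, 0.25)
        ba, bb = np.arange(-50, 51, 1.0), np.arange(0, 60, 1.0)
        _, cnt, _, _ = spatial.hist2d_mean(scene_image, fa, fb, ba, bb)
        sel = scene_image.valid & np.isfinite(fb.d)
        inside = sel & (fa.d >= -50) & (fa.d < 50) & (fb.d >= 0) & (fb.d < 59)
        assert cnt.sum() == inside.sum()

    def test_marginal_equals_decay_profile_exactly(self, scene_image, cross_scene):
        fa = spatial.signed_distance(cross_scene.pattern_mask, 0.25, "pattern_boundary")
        fb = spatial.inward_distance(cross_scene.cell_mask, 0.25)
        ba, bb = np.arange(-20.0, 21.0), np.arange(0.0, 31.0)
        mean, cnt, pho, _ = spatial.hist2d_mean(scene_image, fa, fb, ba, bb)
        with np.errstate(invalid="ignore"):
            marg = np.nansum(np.where(np.isfinite(mean), mean * pho, 0.0), axis=1) / pho.sum(axis=1)
        domain = np.isfinite(fb.d) & (fb.d >= 0) & (fb.d < 30)
        prof = spatial.decay_profile(scene_image, fa, 1.0, fit_range=(-20, 20), domain=domain)
        both = np.isfinite(marg) & np.isfinite(prof.mean_tau)
        assert np.allclose(marg[both], prof.mean_tau[both], rtol=0, atol=1e-12)


class TestDecileRegions:
    def test_exact_counts_with_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(100).astype(float).reshape(10, 10)
        regs = spatial.decile_regions(vals, k=2)
        assert regs["high"].sum() == 20
        assert regs["low"].sum() == 20

    def test_gradient_map_orientation(self):
        vals = np.broadcast_to(np.arange(100.0), (10, 100)).copy()
        regs = spatial.decile_regions(vals)
        assert np.nonzero(regs["high"].any(axis=0))[0].min() == 80
        assert np.nonzero(regs["low"].any(axis=0))[0].max() == 19

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spatial.decile_regions(np.full((10, 10), 4.5))

    def test_regions_within_valid_support(self):
        vals = np.random.default_rng(1).normal(size=(20, 20))
        vals[:5] = np.nan
        regs = spatial.decile_regions(vals)
        assert not regs["high"][:5].any() and not regs["low"][:5].any()


class TestAlignAndAverage:
    def test_single_image_identity(self, cross_scene):
        img = flat_image(cross_scene.cell_mask)
        avg, density, tr = spatial.align_and_average(
            [img], [cross_scene.pattern_mask], cross_scene.pattern_mask)
        sel = cross_scene.cell_mask
        assert np.allclose(avg.tau[sel], 4.5)
        assert tr[0]["iou"] == 1.0

    def test_two_shifted_copies_average_to_one(self, cross_scene):
        img = flat_image(cross_scene.cell_mask)
        tau2 = np.roll(img.tau, (5, -3), axis=(0, 1))
        img2 = LifetimeImage(tau=tau2, photons=np.roll(img.photons, (5, -3), axis=(0, 1)),
                             pixel_size=0.25)
        pat2 = np.roll(cross_scene.pattern_mask, (5, -3), axis=(0, 1))
        avg, density, _ = spatial.align_and_average(
            [img, img2], [cross_scene.pattern_mask, pat2], cross_scene.pattern_mask)
        assert np.allclose(avg.tau[density == 2], 4.5)

    def test_cross_symmetry_rotation_recovered(self, cross_scene):
        img = flat_image(cross_scene.cell_mask)
        rot = LifetimeImage(tau=np.rot90(img.tau), photons=np.rot90(img.photons), pixel_size=0.25)
        avg, _, tr = spatial.align_and_average(
            [rot], [np.rot90(cross_scene.pattern_mask)], cross_scene.pattern_mask,
            symmetry_angles=(0, 90, 180, 270))
        assert tr[0]["iou"] == pytest.approx(1.0)
        assert np.allclose(avg.tau[cross_scene.cell_mask], 4.5)

    def test_poor_overlap_dropped_with_warning(self, cross_scene):
        img = flat_image(cross_scene.cell_mask)
        bad_pat = np.zeros_like(cross_scene.pattern_mask)
        bad_pat[:12, :40] = True  # wrong shape entirely
        with pytest.warns(UserWarning, match="dropped"):
            _, density, tr = spatial.align_and_average(
                [img], [bad_pat], cross_scene.pattern_mask)
        assert tr[0]["dropped"]
        assert density.max() == 0


class TestDifferenceMap:
    def _img(self, tau):
        return LifetimeImage(tau=tau, photons=np.full(tau.shape, 10), pixel_size=0.25)

    def test_condition_equal_reference_gives_zero(self):
        ref = self._img(np.full((8, 8), 4.5))
        deltas, avg = spatial.difference_map([self._img(np.full((8, 8), 4.5))], ref)
        assert np.allclose(avg, 0.0)

    def test_constant_offset_recovered(self):
        ref = self._img(np.full((8, 8), 4.5))
        _, avg = spatial.difference_map([self._img(np.full((8, 8), 4.8))], ref)
        assert np.allclose(avg, 0.3)

    def test_difference_algebra(self):
        rng = np.random.default_rng(3)
        ref = self._img(rng.uniform(4, 5, (8, 8)))
        a = self._img(rng.uniform(4, 5, (8, 8)))
        b = self._img(rng.uniform(4, 5, (8, 8)))
        da, _ = spatial.difference_map([a], ref)
        db, _ = spatial.difference_map([b], ref)
        assert np.allclose(da[0] - db[0], a.tau - b.tau)

    def test_no_common_support_rejected(self):
        ref = self._img(np.full((8, 8), np.nan))
        with pytest.raises(ValueError):
            spatial.difference_map([self._img(np.full((8, 8), np.nan))], ref)


class TestContourProfile:
    def test_flat_field_flat_profile_and_arc_length(self):
        yy, xx = np.mgrid[:200, :200]
        mask = (xx - 100) ** 2 + (yy - 100) ** 2 <= 72**2
        img = flat_image(mask)
        cp = spatial.contour_profile(img, mask)
        r_um = 72 * 0.25
        assert cp.total_length == pytest.approx(2 * np.pi * r_um, rel=0.05)
        ok = np.isfinite(cp.mean_tau)
        assert np.allclose(cp.mean_tau[ok], 4.5)

    def test_profile_is_periodic(self):
        yy, xx = np.mgrid[:100, :100]
        mask = (xx - 50) ** 2 + (yy - 50) ** 2 <= 30**2
        img = flat_image(mask)
        cp = spatial.contour_profile(img, mask)
        assert cp.arc_centers[0] < cp.total_length / 20
        assert cp.total_length - cp.arc_centers[-1] < 1.5 * (cp.arc_centers[1] - cp.arc_centers[0])

    def test_largest_component_used_with_warning(self):
        mask = np.zeros((60, 60), bool)
        mask[5:40, 5:40] = True
        mask[50:54, 50:54] = True
        img = flat_image(mask)
        with pytest.warns(UserWarning, match="components"):
            cp = spatial.contour_profile(img, mask)
        assert cp.total_length > 20  # traced the big square, not the speck
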