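"""FACT, Heiberg-08, EWA and their shared machinery."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lgequant import (
    ContourSet,
    ContractError,
    MethodConfig,
    SliceStack,
    cleanup_artifacts,
    coil_correction,
    em_two_gaussians,
    estimate_remote_auto,
    fact_feature_filter,
    include_mvo,
    rasterize_contours,
    remove_small_components,
    segment_ewa,
    segment_fact,
    segment_heiberg08,
)
from lgequant.geometry import endocardial_distance, midmural_band
from lgequant.phantom import PhantomSpec, circle_polygon, generate_phantom


class TestRemoteAuto:
    def test_phantom_remote_recovered(self, noisy_case):
        est = estimate_remote_auto(noisy_case.stack, noisy_case.mask,
                                   noisy_case.contours)
        assert est.mean == pytest.approx(20.0, rel=0.05)
        # the selected pool avoids the (angle-0) infarct wedge
        assert not np.any(est.voxel_set & noisy_case.truth_support)

    def test_uniform_stack_mean_is_global_mean(self):
        contours = ContourSet({0: {"endo": circle_polygon(20, 20, 8, 128),
                                   "epi": circle_polygon(20, 20, 15, 128)}})
        stack = SliceStack(np.full((41, 41, 1), 7.0), (1, 1), 8.0, "IR")
        mask = rasterize_contours(contours, stack)
        est = estimate_remote_auto(stack, mask, contours)
        assert est.mean == pytest.approx(7.0)
        assert est.sd == 0.0

    def test_contaminated_ring_warns_on_sanity_bound(self):
        # bright/dark mixed wall: no viable sector, high pooled SD
        rng = np.random.default_rng(0)
        contours = ContourSet({0: {"endo": circle_polygon(20, 20, 8, 128),
                                   "epi": circle_polygon(20, 20, 15, 128)}})
        vox = rng.choice([20.0, 200.0], size=(41, 41, 1))
        stack = SliceStack(vox, (1, 1), 8.0, "IR")
        mask = rasterize_contours(contours, stack)
        cfg = MethodConfig(remote_sanity_sd=30.0)
        with pytest.warns(UserWarning, match="sanity"):
            estimate_remote_auto(stack, mask, contours, cfg)

    def test_empty_mask_rejected(self):
        contours = ContourSet({0: {"endo": circle_polygon(20, 20, 8, 64),
                                   "epi": circle_polygon(20, 20, 15, 64)}})
        stack = SliceStack(np.zeros((41, 41, 1)), (1, 1), 8.0, "IR")
        mask = rasterize_contours(contours, stack)
        mask.mask[:] = False
        with pytest.raises(ContractError):
            estimate_remote_auto(stack, mask, contours)


class TestCoilCorrection:
    def test_identity_on_bias_free_stack(self, noise_free_case):
        case = noise_free_case
        corrected, field = coil_correction(case.stack, case.mask)
        rel = np.abs(corrected.voxels[case.mask.mask]
                     - case.stack.voxels[case.mask.mask])
        scale = case.stack.voxels[case.mask.mask].max()
        assert rel.max() <= 0.005 * scale

    def test_linear_ramp_removed(self):
        spec = PhantomSpec(remote_sd=0.0, infarct_sd=0.0, coil_amplitude=0.3)
        case = generate_phantom(spec)
        corrected, _ = coil_correction(case.stack, case.mask)
        band = midmural_band(case.mask, case.contours, case.stack).mask \
            & (case.truth_weights == 0)
        before = case.stack.voxels[band]
        after = corrected.voxels[band]
        cov_before = before.std() / before.mean()
        cov_after = after.std() / after.mean()
        assert cov_before >= 5 * cov_after

    def test_empty_mask_rejected(self, noise_free_case):
        from lgequant.types import MyocardialMask

        empty = MyocardialMask(np.zeros_like(noise_free_case.mask.mask),
                               noise_free_case.mask.geometry)
        with pytest.raises(ContractError):
            coil_correction(noise_free_case.stack, empty)


class TestEm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        n = 4000
        k = rng.random(n) < 0.2
        x = np.where(k, rng.normal(200, 20, n), rng.normal(50, 10, n))
        fit = em_two_gaussians(x)
        assert fit.mean_normal == pytest.approx(50, rel=0.02)
        assert fit.mean_infarct == pytest.approx(200, rel=0.02)
        assert fit.sd_normal == pytest.approx(10, rel=0.10)
        assert fit.sd_infarct == pytest.approx(20, rel=0.10)
        assert fit.mean_infarct > fit.mean_normal

    def test_perfectly_separated_two_point_data(self):
        x = np.array([1.0] * 30 + [9.0] * 10)
        fit = em_two_gaussians(x)
        assert fit.mean_normal == pytest.approx(1.0, abs=1e-6)
        assert fit.mean_infarct == pytest.approx(9.0, abs=1e-6)
        assert fit.weight_infarct == pytest.approx(0.25, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_log_likelihood_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 10.0, size=500)  # skewed, mis-specified input
        fit = em_two_gaussians(x)
        ll = np.array(fit.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_agrees_with_independent_mixture_fitter(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(7)
        n = 5000
        k = rng.random(n) < 0.3
        x = np.where(k, rng.normal(150, 15, n), rng.normal(40, 8, n))
        fit = em_two_gaussians(x)
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        order = np.argsort(gm.means_.ravel())
        ref_means = gm.means_.ravel()[order]
        ref_sds = np.sqrt(gm.covariances_.ravel()[order])
        assert fit.mean_normal == pytest.approx(ref_means[0], rel=0.01)
        assert fit.mean_infarct == pytest.approx(ref_means[1], rel=0.01)
        assert fit.sd_normal == pytest.approx(ref_sds[0], rel=0.05)
        assert fit.sd_infarct == pytest.approx(ref_sds[1], rel=0.05)

    def test_too_few_or_constant_values_rejected(self):
        with pytest.raises(ContractError):
            em_two_gaussians(np.arange(5.0))
        with pytest.raises(ContractError):
            em_two_gaussians(np.full(100, 2.0))


class TestMorphologicalFilters:
    def _stack(self, shape=(20, 20, 1), spacing=(1.0, 1.0), thickness=8.0):
        return SliceStack(np.zeros(shape), spacing, thickness, "IR")

    def test_small_component_removed_at_fact_cutoff(self):
        # 10 voxels of 1x1x8 mm = 0.084 g < 0.1 g -> removed
        sup = np.zeros((20, 20, 1), bool)
        sup[5, 5:15, 0] = True
        out = remove_small_components(sup, self._stack(), min_mass_g=0.1)
        assert not out.any()

    def test_component_exactly_at_cutoff_retained(self):
        sup = np.zeros((20, 20, 1), bool)
        sup[5, 5:15, 0] = True  # 10 voxels x 0.0084 g = 0.084 g exactly
        out = remove_small_components(sup, self._stack(), min_mass_g=0.084)
        assert out.sum() == 10

    def test_empty_support_passthrough(self):
        sup = np.zeros((20, 20, 1), bool)
        assert not remove_small_components(sup, self._stack(), min_mass_g=0.1).any()

    def test_cleanup_keeps_largest_drops_specks(self):
        from lgequant.types import MyocardialMask, SliceGeometry

        sup = np.zeros((30, 30, 1), bool)
        sup[5:15, 5:15, 0] = True  # large block
        sup[25, 25, 0] = True  # isolated speck, 0.0084 g
        mask = MyocardialMask(np.ones((30, 30, 1), bool), SliceGeometry((1, 1), 8))
        out = cleanup_artifacts(sup, self._stack((30, 30, 1)), mask, 0.1)
        # opening shaves at most the block corners; the interior survives
        assert out[6:14, 6:14, 0].all()
        assert not out[25, 25, 0]
        assert np.all(sup[out])


class TestIncludeMvo:
    def _geometry(self):
        contours = ContourSet({0: {"endo": circle_polygon(20, 20, 8, 128),
                                   "epi": circle_polygon(20, 20, 16, 128)}})
        stack = SliceStack(np.zeros((41, 41, 1)), (1, 1), 8.0, "IR")
        mask = rasterize_contours(contours, stack)
        return contours, stack, mask

    def test_core_ringed_by_infarct_is_filled(self):
        contours, stack, mask = self._geometry()
        support = mask.mask.copy()
        support[19:22, 19:26, 0] = False  # interior dark pocket (inside wall ring)
        # carve the pocket strictly inside supported wall: pick wall voxels
        support = mask.mask.copy()
        rr, cc = np.nonzero(mask.mask[:, :, 0])
        # a 1-voxel hole in the middle of the wall thickness at angle 0
        hole = (32, 20)
        assert mask.mask[hole[0], hole[1], 0]
        support[hole[0], hole[1], 0] = False
        out = include_mvo(support, mask, contours, stack)
        assert out[hole[0], hole[1], 0]

    def test_region_touching_epicardium_not_filled(self):
        contours, stack, mask = self._geometry()
        support = mask.mask.copy()
        # open a radial notch from mid-wall to the epicardial border at angle 0
        support[19:22, 30:37, 0] = False
        out = include_mvo(support, mask, contours, stack)
        assert not out[20, 35, 0]

    def test_phantom_mvo_core_recovered_by_fact(self, mvo_case):
        seg = segment_fact(mvo_case.stack, mvo_case.contours)
        assert seg.fraction_of_LV_percent == pytest.approx(
            mvo_case.truth_fraction_percent, abs=2.0
        )
        # the dark core itself is segmented
        core = mvo_case.truth_support \
            & (mvo_case.stack.voxels < 15.0)
        assert core.any() and np.all(seg.support[core])


class TestFactFilter:
    def test_exactly_the_three_bad_blobs_removed(self):
        contours = ContourSet({0: {"endo": circle_polygon(30, 30, 10, 128),
                                   "epi": circle_polygon(30, 30, 25, 128)}})
        vox = np.zeros((61, 61, 1))
        stack = SliceStack(vox, (1.0, 1.0), 8.0, "IR")
        mask = rasterize_contours(contours, stack)
        sup = np.zeros((61, 61, 1), bool)
        # A: 10 voxels (0.084 g < 0.1 g), adjacent to endo, bright
        sup[28:33, 41:43, 0] = True
        vox[28:33, 41:43, 0] = 100.0
        # B: big bright blob but > 3 mm from the endocardium
        sup[8:12, 24:36, 0] = True
        vox[8:12, 24:36, 0] = 100.0
        # C: big blob near endo but low intensity (< 50% of pooled mean)
        sup[41:45, 24:36, 0] = True
        vox[41:45, 24:36, 0] = 20.0
        # D: a compliant blob (big, subendocardial, bright)
        sup[26:35, 15:19, 0] = True
        vox[26:35, 15:19, 0] = 100.0
        sup &= mask.mask
        endo_dist = endocardial_distance(mask, contours, stack)
        out, removed = fact_feature_filter(sup, stack, mask, endo_dist)
        reasons = {r["reasons"][0] for r in removed}
        assert len(removed) == 3
        assert reasons == {"mass", "endo_distance", "intensity"}
        assert out[26:35, 15:19, 0].any() and not out[8:12, 24:36, 0].any()


class TestPipelines:
    def test_fact_recovers_noise_free_truth(self, noise_free_case):
        seg = segment_fact(noise_free_case.stack, noise_free_case.contours)
        assert seg.fraction_of_LV_percent == pytest.approx(
            noise_free_case.truth_fraction_percent, abs=1.5
        )

    def test_heiberg_recovers_noise_free_truth(self, noise_free_case):
        seg = segment_heiberg08(noise_free_case.stack, noise_free_case.contours)
        assert seg.fraction_of_LV_percent == pytest.approx(
            noise_free_case.truth_fraction_percent, abs=2.0
        )

    def test_ewa_recovers_noise_free_truth(self, noise_free_case):
        seg = segment_ewa(noise_free_case.stack, noise_free_case.contours)
        assert seg.fraction_of_LV_percent == pytest.approx(
            noise_free_case.truth_fraction_percent, abs=1.0
        )

    def test_heiberg_refuses_psir(self, psir_case):
        with pytest.raises(ContractError, match="PSIR"):
            segment_heiberg08(psir_case.stack, psir_case.contours)

    def test_ewa_and_fact_accept_psir(self, psir_case):
        for fn in (segment_ewa, segment_fact):
            seg = fn(psir_case.stack, psir_case.contours)
            assert seg.fraction_of_LV_percent == pytest.approx(
                psir_case.truth_fraction_percent, abs=2.0
            )

    def test_weighted_fraction_below_binary_support_fraction(self, noisy_case):
        from lgequant.geometry import infarct_size

        for fn in (segment_ewa, segment_heiberg08):
            seg = fn(noisy_case.stack, noisy_case.contours)
            binary = infarct_size(seg.support.astype(float), noisy_case.mask)[2]
            assert seg.fraction_of_LV_percent <= binary + 1e-9

    def test_ewa_zero_on_pure_remote(self, null_case):
        with pytest.warns(UserWarning, match="no infarct evidence"):
            seg = segment_ewa(null_case.stack, null_case.contours)
        assert seg.fraction_of_LV_percent == 0.0

    def test_fact_and_heiberg_zero_on_pure_remote(self, null_case):
        assert segment_fact(null_case.stack, null_case.contours) \
            .fraction_of_LV_percent == 0.0
        assert segment_heiberg08(null_case.stack, null_case.contours) \
            .fraction_of_LV_percent == 0.0

    def test_ewa_invariant_to_coil_ramp(self):
        base = generate_phantom(PhantomSpec(seed=21))
        ramped = generate_phantom(PhantomSpec(seed=21, coil_amplitude=0.3))
        f0 = segment_ewa(base.stack, base.contours).fraction_of_LV_percent
        f1 = segment_ewa(ramped.stack, ramped.contours).fraction_of_LV_percent
        assert abs(f0 - f1) <= 0.5

    def test_fwhm_anchors_coincide_when_remote_mean_is_zero(self):
        from lgequant import fwhm_threshold

        values = np.array([0.0, 40.0, 80.0])
        t0 = fwhm_threshold(values, anchor="zero").value
        tr = fwhm_threshold(values, anchor="remote", remote_mean=0.0).value
        assert t0 == tr
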