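"""Deconvolution core: baseline handling, AIF selection, Tikhonov
inversion, map computation and motion correction."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from ctperf import (DeconvConfig, DynamicSeries, PhantomSpec, TissueParams,
                    TikhonovDeconvolver, baseline_subtract, build_phantom,
                    compute_maps, correct_motion, deconvolve_tikhonov,
                    estimate_baseline_frames, hemisphere_masks, motion_index,
                    select_aif, tissue_curve)
from conftest import SMALL_LESION, small_spec


def _interp(t_frames, t_dense, curve):
    return np.interp(t_frames, t_dense, curve)


class TestBaselineSubtract:
    def test_constant_series_maps_to_zero(self):
        s = DynamicSeries(np.full((10, 2, 2, 2), 40.0), 1.5, (5, 2, 2))
        assert np.all(baseline_subtract(s, 3).data == 0.0)

    def test_global_offset_invariance(self, lesion_case):
        s = lesion_case.series
        shifted = DynamicSeries(s.data + 40.0, s.dt, s.voxel_size_mm)
        a = baseline_subtract(s, 4).data
        b = baseline_subtract(shifted, 4).data
        assert np.allclose(a, b)

    def test_residual_baseline_shrinks_with_averaging(self):
        """Mean of the pre-contrast residual behaves like a mean of n
        noise samples."""
        spec = small_spec(lesion=None)
        case = build_phantom(spec, seed=3)
        conc = baseline_subtract(case.series, 5)
        residual = conc.data[:5].mean()
        n_vox = np.prod(case.series.shape) * 5
        assert abs(residual) < 4 * spec.noise_sigma / np.sqrt(n_vox)

    @pytest.mark.parametrize("n", [0, 27, 40])
    def test_out_of_range_baseline_rejected(self, n):
        s = DynamicSeries(np.zeros((27, 2, 2, 2)), 1.5, (5, 2, 2))
        with pytest.raises(ValueError):
            baseline_subtract(s, n)

    def test_baseline_estimate_covers_precontrast_frames(self, lesion_case):
        n = estimate_baseline_frames(lesion_case.series, lesion_case.masks["brain"])
        # bolus arrives at t0 >= 6.5 s, so at least frames 0-3 are pre-contrast
        assert 2 <= n <= 7


class TestSelectAif:
    def test_manual_single_voxel_returns_that_curve(self, noiseless_case):
        conc = baseline_subtract(noiseless_case.series, 4)
        mask = np.zeros(noiseless_case.series.shape, bool)
        mask[2, 10, 30] = True
        aif = select_aif(conc, noiseless_case.masks["brain"], manual_mask=mask)
        expected = np.clip(conc.data[:, 2, 10, 30], 0, None)
        assert np.allclose(aif.values, expected)
        assert aif.source == "manual"

    def test_automatic_selection_lands_in_artery(self, noiseless_case):
        conc = baseline_subtract(noiseless_case.series, 4)
        aif = select_aif(conc, noiseless_case.masks["brain"])
        art = noiseless_case.masks["artery"]
        hits = sum(art[z, y, x] for z, y, x in aif.voxel_indices)
        assert hits == len(aif.voxel_indices)

    def test_selected_peak_dominates_mean_brain_peak(self, noiseless_case):
        conc = baseline_subtract(noiseless_case.series, 4)
        aif = select_aif(conc, noiseless_case.masks["brain"])
        mean_peak = conc.data[:, noiseless_case.masks["brain"]].mean(axis=1).max()
        assert aif.values.max() >= mean_peak

    def test_empty_mask_rejected(self, noiseless_case):
        conc = baseline_subtract(noiseless_case.series, 4)
        with pytest.raises(ValueError):
            select_aif(conc, np.zeros(conc.shape, bool))
        with pytest.raises(ValueError):
            select_aif(conc, noiseless_case.masks["brain"],
                       manual_mask=np.zeros(conc.shape, bool))


class TestTikhonovDeconvolution:
    def test_unregularised_inversion_is_exact(self, dense_forward):
        """lambda = 0: data generated by the discrete operator itself are
        inverted to machine precision (operator built independently here)."""
        spec = PhantomSpec()
        tf = spec.frame_times
        t, aif_d = dense_forward
        aif = _interp(tf, t, aif_d)
        n, n_pad = 27, 54
        padded = np.zeros(n_pad)
        padded[:n] = aif
        idx = (np.arange(n_pad)[:, None] - np.arange(n_pad)[None, :]) % n_pad
        a_mat = spec.dt * padded[idx]          # independent circulant build
        k_true = np.zeros(n_pad)
        k_true[:n] = 0.6 * np.exp(-tf / 4.0)
        c_full = a_mat @ k_true
        k_rec = deconvolve_tikhonov(c_full, aif, spec.dt,
                                    DeconvConfig(lambda_rel=0.0))
        err = np.abs(k_rec - k_true[:n]).max() / np.abs(k_true).max()
        assert err < 1e-6

    def test_flow_ratio_recovered_within_5pct(self, dense_forward):
        """Forward model at dt = 0.1 s as oracle: relative CBF (max k vs a
        normal-tissue reference) is recovered within 5% at default lambda."""
        spec = PhantomSpec()
        tf = spec.frame_times
        t, aif_d = dense_forward
        aif = _interp(tf, t, aif_d)
        dec = TikhonovDeconvolver(aif, spec.dt)
        ref = dec.solve(_interp(tf, t, tissue_curve(aif_d, TissueParams(1.0, 4.0, 0.0), 0.1))).max()
        for cbf, delay in [(0.6, 0.0), (0.6, 8.0)]:
            c = _interp(tf, t, tissue_curve(aif_d, TissueParams(cbf, 4.0, delay), 0.1))
            ratio = dec.solve(c).max() / ref
            assert ratio == pytest.approx(cbf, rel=0.05)

    def test_arrival_delay_recovered_within_one_sample(self, dense_forward):
        spec = PhantomSpec()
        tf = spec.frame_times
        t, aif_d = dense_forward
        aif = _interp(tf, t, aif_d)
        dec = TikhonovDeconvolver(aif, spec.dt)
        c = _interp(tf, t, tissue_curve(aif_d, TissueParams(0.6, 4.0, 8.0), 0.1))
        tmax = dec.solve(c).argmax() * spec.dt
        assert abs(tmax - 8.0) <= spec.dt

    def test_zero_aif_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            TikhonovDeconvolver(np.zeros(27), 1.5)

    def test_batched_solve_matches_single(self, dense_forward):
        spec = PhantomSpec()
        tf = spec.frame_times
        t, aif_d = dense_forward
        aif = _interp(tf, t, aif_d)
        dec = TikhonovDeconvolver(aif, spec.dt)
        c1 = _interp(tf, t, tissue_curve(aif_d, TissueParams(0.6, 4.0, 0.0), 0.1))
        c2 = _interp(tf, t, tissue_curve(aif_d, TissueParams(0.3, 6.0, 5.0), 0.1))
        batch = dec.solve(np.column_stack([c1, c2]))
        assert np.allclose(batch[:, 0], dec.solve(c1))
        assert np.allclose(batch[:, 1], dec.solve(c2))


class TestComputeMaps:
    def test_homogeneous_phantom_normalises_to_100(self):
        case = build_phantom(small_spec(lesion=None), seed=11)
        maps = compute_maps(case.series, brain_mask=case.masks["brain"])
        normal = case.masks["brain"] & ~case.masks["artery"]
        assert np.median(maps.cbf_rel[normal]) == pytest.approx(100.0, abs=5.0)
        assert maps.cbf_rel[normal].std() < 15.0

    def test_contralateral_mean_is_exactly_100(self, noiseless_maps):
        hemis = hemisphere_masks(noiseless_maps.cbf_rel.shape)
        ref = hemis[noiseless_maps.contralateral] & noiseless_maps.valid_mask
        assert noiseless_maps.cbf_rel[ref].mean() == pytest.approx(100.0)
        assert noiseless_maps.cbv_rel[ref].mean() == pytest.approx(100.0)

    def test_contralateral_is_unlesioned_hemisphere(self, noiseless_maps):
        assert noiseless_maps.contralateral == "right"

    def test_lesion_cbf_and_cbv_recovered(self, noiseless_case, noiseless_maps):
        """Interior lesion voxels recover the prescribed relative CBF and
        (via the central-volume theorem) relative CBV."""
        core = binary_erosion(noiseless_case.masks["core"], np.ones((1, 3, 3), bool))
        assert core.any()
        cbf_med = np.median(noiseless_maps.cbf_rel[core])
        truth = SMALL_LESION.core.cbf_rel * 100
        assert truth * 0.7 < cbf_med < 30.0   # below the core threshold
        cbv_med = np.median(noiseless_maps.cbv_rel[core])
        assert cbv_med == pytest.approx(SMALL_LESION.core.cbv_rel * 100, rel=0.25)

    def test_lesion_tmax_tracks_delay(self, noiseless_case, noiseless_maps):
        """Recovered Tmax reflects the arrival delay up to the documented
        one-to-two sample onset bias, and normal tissue stays under 6 s."""
        # full-severity penumbra band (the edge ramp tapers towards normal)
        pen = noiseless_case.masks["penumbra"] \
            & (noiseless_case.delay_map == SMALL_LESION.penumbra.delay)
        assert pen.any()
        normal = noiseless_case.masks["brain"] & ~noiseless_case.masks["hypoperfusion"] \
            & ~noiseless_case.masks["artery"]
        dt = noiseless_maps.dt
        tmax_pen = np.median(noiseless_maps.tmax[pen])
        delay = SMALL_LESION.penumbra.delay
        assert delay - dt <= tmax_pen <= delay + 2 * dt
        assert np.median(noiseless_maps.tmax[normal]) < 6.0

    def test_valid_mask_drops_zero_flow_voxels(self):
        case = build_phantom(small_spec(lesion=None, noise_sigma=0.0), seed=2)
        maps = compute_maps(case.series, brain_mask=case.masks["brain"])
        assert np.isnan(maps.mtt[~maps.valid_mask & maps.brain_mask]).all()


class TestMotion:
    def test_static_series_unchanged(self, noiseless_case):
        corrected, shifts = correct_motion(noiseless_case.series,
                                           noiseless_case.masks["brain"])
        assert np.array_equal(corrected.data, noiseless_case.series.data)
        assert not shifts.any()

    def test_known_shift_recovered(self):
        case = build_phantom(small_spec(lesion=None), seed=21)
        data = case.series.data.copy()
        for t in range(10, 20):
            data[t] = np.roll(data[t], 3, axis=2)   # +3 voxels along x
        moved = DynamicSeries(data, case.series.dt, case.series.voxel_size_mm)
        _, shifts = correct_motion(moved, case.masks["brain"])
        assert np.all(shifts[10:20] == (0, -3))
        assert not shifts[:10].any() and not shifts[20:].any()

    def test_correction_raises_motion_index(self):
        case = build_phantom(small_spec(lesion=None, scenario="motion"), seed=21)
        before = np.nanmin(motion_index(case.series, case.masks["brain"]))
        corrected, _ = correct_motion(case.series, case.masks["brain"])
        after = np.nanmin(motion_index(corrected, case.masks["brain"]))
        assert after >= before
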