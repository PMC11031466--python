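"""Segmentation thresholds, volumetry arithmetic, DEFUSE-3 logic and the
margin-filtered confusion matrix."""

import numpy as np
import pytest

from ctperf import (ConfusionMatrix, Defuse3Thresholds, LesionReport,
                    compare_decisions, defuse3_decide, segment, volumetry)
from ctperf.perfusion import PerfusionMaps


def _maps(tmax, cbf):
    tmax = np.asarray(tmax, float)
    cbf = np.asarray(cbf, float)
    valid = np.ones(tmax.shape, bool)
    return PerfusionMaps(cbf_rel=cbf, cbv_rel=cbf.copy(), tmax=tmax,
                         mtt=np.ones_like(tmax), brain_mask=valid.copy(),
                         valid_mask=valid, contralateral="right", dt=1.5,
                         voxel_size_mm=(10.0, 10.0, 10.0))


def _report(hypo, core):
    """LesionReport from volumes in mL (1 mL voxels)."""
    ratio = hypo / core if core > 0 else float("nan")
    return LesionReport(hypo, core, hypo - core, ratio, core > 3.0)


class TestSegment:
    def test_normal_maps_give_empty_masks(self):
        maps = _maps(np.full((2, 2, 2), 3.0), np.full((2, 2, 2), 100.0))
        hypo, core = segment(maps)
        assert not hypo.any() and not core.any()

    def test_tmax_threshold_is_strict(self):
        maps = _maps([[[6.0, 6.01]]], [[[10.0, 10.0]]])
        hypo, _ = segment(maps)
        assert hypo.tolist() == [[[False, True]]]

    def test_cbf_threshold_is_strict(self):
        maps = _maps([[[9.0, 9.0]]], [[[30.0, 29.99]]])
        _, core = segment(maps)
        assert core.tolist() == [[[False, True]]]

    def test_core_nested_within_hypoperfusion_by_default(self):
        # low CBF but normal Tmax: not core under the nesting convention
        maps = _maps([[[3.0]]], [[[10.0]]])
        hypo, core = segment(maps)
        assert not core.any()
        hypo, core = segment(maps, nested=False)
        assert core.any() and not hypo.any()


class TestVolumetry:
    def test_arithmetic(self):
        hypo = np.zeros(30, bool); hypo[:20] = True
        core = np.zeros(30, bool); core[:5] = True
        rep = volumetry(hypo, core, voxel_volume_ml=1.0)
        assert rep.hypoperfusion_volume == 20.0
        assert rep.core_volume == 5.0
        assert rep.mismatch_volume == 15.0
        assert rep.mismatch_ratio == pytest.approx(4.0)
        assert rep.ratio_evaluable

    def test_small_core_not_ratio_evaluable(self):
        hypo = np.ones(10, bool)
        core = np.zeros(10, bool); core[:2] = True
        rep = volumetry(hypo, core, voxel_volume_ml=1.0)
        assert rep.core_volume == 2.0
        assert not rep.ratio_evaluable

    def test_empty_masks(self):
        rep = volumetry(np.zeros(5, bool), np.zeros(5, bool), 1.0)
        assert rep.hypoperfusion_volume == rep.core_volume == rep.mismatch_volume == 0.0
        assert np.isnan(rep.mismatch_ratio)
        assert not rep.ratio_evaluable

    def test_unnested_core_rejected(self):
        hypo = np.zeros(4, bool); hypo[0] = True
        core = np.zeros(4, bool); core[1] = True
        with pytest.raises(ValueError):
            volumetry(hypo, core, 1.0)


class TestDefuse3:
    def test_clear_treat_case(self):
        d = defuse3_decide(_report(110.0, 50.0))
        assert d.treat and not d.in_margin_zone

    def test_large_core_blocks_treatment(self):
        d = defuse3_decide(_report(200.0, 80.0))
        assert not d.treat and not d.core_ok

    def test_core_near_threshold_is_margin_zone(self):
        assert defuse3_decide(_report(150.0, 68.0)).in_margin_zone

    def test_zero_core_with_hypoperfusion_satisfies_ratio(self):
        d = defuse3_decide(_report(40.0, 0.0))
        assert d.ratio_ok and d.treat
        assert not d.in_margin_zone

    def test_zero_core_zero_hypoperfusion_is_no_treat(self):
        d = defuse3_decide(_report(0.0, 0.0))
        assert not d.treat

    def test_exhaustive_grid_around_thresholds(self):
        """Strict-inequality semantics and margin membership across a grid
        straddling all three thresholds and their margin zones."""
        thr = Defuse3Thresholds()
        for core in [0.0, 2.0, 20.0, 60.0, 64.9, 65.0, 70.0, 75.0, 75.1, 90.0]:
            for mismatch in [0.0, 9.9, 10.0, 15.0, 20.0, 20.1, 50.0]:
                hypo = core + mismatch
                rep = _report(hypo, core)
                d = defuse3_decide(rep, thr)
                ratio_ok = (hypo / core > 1.8) if core > 0 else hypo > 0
                assert d.treat == (core < 70.0 and mismatch > 15.0 and ratio_ok)
                in_margin = (65.0 <= core <= 75.0) or (10.0 <= mismatch <= 20.0)
                if core > 0 and 1.6 <= hypo / core <= 2.0:
                    in_margin = True
                assert d.in_margin_zone == in_margin

    def test_decision_monotone_in_core_volume(self):
        """Shrinking the core (others fixed, outside margins) never flips
        treat into no-treat."""
        mismatch = 40.0
        prev_treat = False
        for core in [120.0, 90.0, 60.0, 30.0, 10.0, 4.0]:
            d = defuse3_decide(_report(core + mismatch, core))
            if prev_treat:
                assert d.treat
            prev_treat = d.treat
        assert prev_treat


class TestCompareDecisions:
    def test_identical_lists_are_diagonal(self):
        decisions = [defuse3_decide(_report(h, c))
                     for h, c in [(110, 50), (200, 80), (30, 2), (0, 0)]]
        cm = compare_decisions(decisions, decisions)
        assert cm.fp == cm.fn == 0
        assert cm.percentages["tp"] == 100.0
        assert cm.percentages["tn"] == 100.0

    def test_hand_enumerated_counts(self):
        treat = defuse3_decide(_report(110.0, 50.0))
        no = defuse3_decide(_report(200.0, 120.0))
        cm = compare_decisions([treat, treat, no], [treat, no, no],
                               exclude_margin=False)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 0, 1)
        assert cm.n_discordant == 1

    def test_margin_cases_excluded_before_counting(self):
        margin = defuse3_decide(_report(150.0, 68.0))     # core in 65-75
        clear = defuse3_decide(_report(110.0, 50.0))
        cm = compare_decisions([margin, clear], [clear, clear])
        assert cm.n_excluded_margin == 1
        assert cm.n_counted == 1

    def test_all_margin_gives_empty_matrix(self):
        margin = defuse3_decide(_report(150.0, 68.0))
        cm = compare_decisions([margin] * 3, [margin] * 3)
        assert cm.n_counted == 0 and cm.n_excluded_margin == 3

    def test_margin_exclusion_never_increases_discordance(self):
        rng = np.random.default_rng(0)
        refs, tests = [], []
        for _ in range(100):
            core = float(rng.uniform(0, 120))
            mism = float(rng.uniform(0, 60))
            refs.append(defuse3_decide(_report(core + mism, core)))
            core2 = max(0.0, core + rng.normal(0, 8))
            mism2 = max(0.0, mism + rng.normal(0, 8))
            tests.append(defuse3_decide(_report(core2 + mism2, core2)))
        with_excl = compare_decisions(refs, tests, exclude_margin=True)
        without = compare_decisions(refs, tests, exclude_margin=False)
        assert with_excl.n_discordant <= without.n_discordant

    def test_length_mismatch_rejected(self):
        d = defuse3_decide(_report(110.0, 50.0))
        with pytest.raises(ValueError):
            compare_decisions([d], [d, d])

    def test_percentage_rows_sum_to_100(self):
        treat = defuse3_decide(_report(110.0, 50.0))
        no = defuse3_decide(_report(200.0, 120.0))
        cm = compare_decisions([treat, treat, no, no], [treat, no, no, treat],
                               exclude_margin=False)
        p = cm.percentages
        assert p["tp"] + p["fn"] == pytest.approx(100.0)
        assert p["fp"] + p["tn"] == pytest.approx(100.0)
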