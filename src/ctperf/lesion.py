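"""Lesion segmentation, volumetry and DEFUSE-3 treatment decisions.

Operational definitions (the established perfusion-CT thresholds):
hypoperfusion is Tmax > 6 s; infarct core is relative CBF < 30% of the
contralateral mean, nested inside the hypoperfused region; mismatch
(penumbra) is hypoperfusion minus core. The DEFUSE-3 perfusion criteria
call for thrombectomy when core < 70 mL, mismatch > 15 mL and mismatch
ratio (hypoperfusion / core) > 1.8. When paired decisions at two temporal
samplings are compared, cases whose reference values fall inside a margin
zone around the thresholds (core 65-75 mL, mismatch 10-20 mL, ratio
1.6-2.0) are excluded before counting, reflecting the finite measurement
precision near a decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .perfusion import PerfusionMaps

__all__ = [
    "SegmentationThresholds",
    "Defuse3Thresholds",
    "LesionReport",
    "Defuse3Decision",
    "ConfusionMatrix",
    "segment",
    "volumetry",
    "defuse3_decide",
    "compare_decisions",
]


@dataclass(frozen=True)
class SegmentationThresholds:
    tmax_s: float = 6.0            # hypoperfusion: Tmax strictly above this
    cbf_pct: float = 30.0          # core: relative CBF strictly below this
    core_evaluable_ml: float = 3.0 # mismatch ratio reported above this core


@dataclass(frozen=True)
class Defuse3Thresholds:
    core_max_ml: float = 70.0
    mismatch_min_ml: float = 15.0
    ratio_min: float = 1.8
    volume_margin_ml: float = 5.0  # half-width of the volume margin zones
    ratio_margin: float = 0.2


@dataclass
class LesionReport:
    """Volumetry of one case at one sampling (volumes in mL)."""

    hypoperfusion_volume: float
    core_volume: float
    mismatch_volume: float
    mismatch_ratio: float          # nan when undefined (core volume 0)
    ratio_evaluable: bool          # core volume above the 3 mL floor

    def to_dict(self) -> dict:
        return {
            "hypoperfusion_volume_ml": self.hypoperfusion_volume,
            "core_volume_ml": self.core_volume,
            "mismatch_volume_ml": self.mismatch_volume,
            "mismatch_ratio": None if np.isnan(self.mismatch_ratio) else self.mismatch_ratio,
            "ratio_evaluable": self.ratio_evaluable,
        }


@dataclass
class Defuse3Decision:
    """Treat / no-treat call with the per-criterion breakdown."""

    treat: bool
    in_margin_zone: bool
    core_ok: bool
    mismatch_ok: bool
    ratio_ok: bool

    @property
    def eligible(self) -> str:
        return "treat" if self.treat else "no_treat"

    def to_dict(self) -> dict:
        return {"eligible": self.eligible, "in_margin_zone": self.in_margin_zone,
                "core_ok": self.core_ok, "mismatch_ok": self.mismatch_ok,
                "ratio_ok": self.ratio_ok}


@dataclass
class ConfusionMatrix:
    """Treat/no-treat agreement against the reference sampling.

    Rows are the reference decision, columns the test decision; counts are
    taken after excluding reference-margin cases. Percentages are
    normalised within each reference row.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    n_excluded_margin: int

    @property
    def n_counted(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_discordant(self) -> int:
        return self.fn + self.fp

    @property
    def discordance_rate(self) -> float:
        return self.n_discordant / self.n_counted if self.n_counted else np.nan

    @property
    def percentages(self) -> dict[str, float]:
        """Row-normalised percentages (each reference row sums to 100)."""
        pos = self.tp + self.fn
        neg = self.fp + self.tn
        return {
            "tp": 100.0 * self.tp / pos if pos else np.nan,
            "fn": 100.0 * self.fn / pos if pos else np.nan,
            "fp": 100.0 * self.fp / neg if neg else np.nan,
            "tn": 100.0 * self.tn / neg if neg else np.nan,
        }

    def to_frame(self):
        """Counts and row percentages in the conventional 2x2 layout."""
        import pandas as pd

        pct = self.percentages
        return pd.DataFrame(
            {
                "test +": [self.tp, self.fp, pct["tp"], pct["fp"]],
                "test -": [self.fn, self.tn, pct["fn"], pct["tn"]],
            },
            index=["ref + (n)", "ref - (n)", "ref + (%)", "ref - (%)"],
        )


def segment(maps: PerfusionMaps,
            thresholds: SegmentationThresholds | None = None,
            nested: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the maps into (hypoperfusion, core) masks.

    Both thresholds are strict inequalities; voxels with undefined MTT
    (zero recovered flow) are excluded. With ``nested`` (the default and
    the DEFUSE-3 operational convention) the core is intersected with the
    hypoperfusion mask, guaranteeing mismatch >= 0.
    """
    thr = thresholds or SegmentationThresholds()
    valid = maps.valid_mask
    hypo = valid & (maps.tmax > thr.tmax_s)
    core = valid & (maps.cbf_rel < thr.cbf_pct)
    if nested:
        core = core & hypo
    return hypo, core


def volumetry(hypo_mask: np.ndarray, core_mask: np.ndarray,
              voxel_volume_ml: float,
              core_evaluable_ml: float = 3.0) -> LesionReport:
    """Volumes, mismatch and mismatch ratio from the two masks."""
    if np.any(core_mask & ~hypo_mask):
        raise ValueError("core mask must be nested inside the hypoperfusion mask")
    hypo_ml = float(hypo_mask.sum()) * voxel_volume_ml
    core_ml = float(core_mask.sum()) * voxel_volume_ml
    mismatch = hypo_ml - core_ml
    ratio = hypo_ml / core_ml if core_ml > 0 else np.nan
    return LesionReport(hypo_ml, core_ml, mismatch, ratio,
                        ratio_evaluable=core_ml > core_evaluable_ml)


def _in_margin(report: LesionReport, thr: Defuse3Thresholds) -> bool:
    core, mism, ratio = (report.core_volume, report.mismatch_volume,
                         report.mismatch_ratio)
    dv, dr = thr.volume_margin_ml, thr.ratio_margin
    if thr.core_max_ml - dv <= core <= thr.core_max_ml + dv:
        return True
    if thr.mismatch_min_ml - dv <= mism <= thr.mismatch_min_ml + dv:
        return True
    if np.isfinite(ratio) and thr.ratio_min - dr <= ratio <= thr.ratio_min + dr:
        return True
    return False


def defuse3_decide(report: LesionReport,
                   thresholds: Defuse3Thresholds | None = None) -> Defuse3Decision:
    """Apply the DEFUSE-3 perfusion criteria to one volumetry report.

    All three criteria are strict inequalities. When the core volume is
    zero the ratio is undefined; the ratio criterion is then taken as
    satisfied whenever any hypoperfusion is present (the limit of
    hypoperfusion/core as core -> 0), which is the clinically intended
    reading. The margin-zone test is unaffected by that convention.
    """
    thr = thresholds or Defuse3Thresholds()
    core_ok = report.core_volume < thr.core_max_ml
    mismatch_ok = report.mismatch_volume > thr.mismatch_min_ml
    if np.isfinite(report.mismatch_ratio):
        ratio_ok = report.mismatch_ratio > thr.ratio_min
    else:
        ratio_ok = report.hypoperfusion_volume > 0
    return Defuse3Decision(
        treat=core_ok and mismatch_ok and ratio_ok,
        in_margin_zone=_in_margin(report, thr),
        core_ok=core_ok, mismatch_ok=mismatch_ok, ratio_ok=ratio_ok,
    )


def compare_decisions(reference: Sequence[Defuse3Decision],
                      test: Sequence[Defuse3Decision],
                      exclude_margin: bool = True) -> ConfusionMatrix:
    """Confusion matrix of test decisions against the reference sampling.

    Cases flagged in the margin zone on the *reference* are excluded
    before counting (when ``exclude_margin``). TP/FN/FP/TN follow the
    convention rows = reference, columns = test, positive = treat.
    """
    if len(reference) != len(test):
        raise ValueError("reference and test decision lists differ in length")
    tp = fn = fp = tn = excluded = 0
    for ref, tst in zip(reference, test):
        if exclude_margin and ref.in_margin_zone:
            excluded += 1
            continue
        if ref.treat and tst.treat:
            tp += 1
        elif ref.treat:
            fn += 1
        elif tst.treat:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fn, fp, tn, excluded)
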