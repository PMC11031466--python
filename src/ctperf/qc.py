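"""Automated quality control of dynamic perfusion acquisitions.

Three rules, each evaluated on the mean brain bolus curve or the raw frame
stack, flag the acquisition problems that corrupt perfusion quantification:

- truncated bolus: the mean-brain contrast peak occurs later than 90% of
  the acquisition window, so the downslope is not captured;
- low contrast-to-noise: the mean-brain bolus peak is below 8 HU;
- motion: the Pearson correlation of any frame with the first frame
  (the motion index) drops below 0.7.

A case with no flags is classed as high quality, otherwise impaired. A
stricter "uninterpretable" state (zero-variance bolus or motion index
below 0.3) stands in for the fatal failures that in practice are caught by
visual review and removed from analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import DynamicSeries
from .perfusion import (baseline_subtract, estimate_baseline_frames,
                        motion_index)

__all__ = ["QCThresholds", "QCReport", "mean_bolus_curve", "evaluate_qc",
           "motion_index"]


@dataclass(frozen=True)
class QCThresholds:
    peak_position_max: float = 0.90      # fraction of the acquisition window
    peak_height_min_hu: float = 8.0
    motion_index_min: float = 0.7
    motion_index_fatal: float = 0.3


@dataclass
class QCReport:
    """Outcome of automated QC for one series at one sampling."""

    peak_position_fraction: float
    peak_height_hu: float
    motion_index: np.ndarray
    min_motion_index: float
    flags: dict[str, bool]
    quality_class: str                   # "high" | "impaired"
    uninterpretable: bool
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_dict(self) -> dict:
        return {
            "peak_position_fraction": float(self.peak_position_fraction),
            "peak_height_hu": float(self.peak_height_hu),
            "min_motion_index": float(self.min_motion_index),
            "motion_index": [float(v) for v in self.motion_index],
            "flags": {k: bool(v) for k, v in self.flags.items()},
            "quality_class": self.quality_class,
            "uninterpretable": bool(self.uninterpretable),
        }


def mean_bolus_curve(conc: DynamicSeries, brain_mask: np.ndarray) -> np.ndarray:
    """Frame-wise mean of a baseline-subtracted series over the brain mask."""
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    return conc.data[:, brain_mask].mean(axis=1)


def evaluate_qc(series: DynamicSeries, brain_mask: np.ndarray | None = None,
                thresholds: QCThresholds | None = None,
                n_baseline: int | None = None) -> QCReport:
    """Apply the three automated rules to a raw HU series.

    The bolus metrics are computed on the raw (unsmoothed) mean brain
    curve after baseline subtraction; the acquisition window is
    (n_frames - 1) * dt of the series under evaluation, so a decimated
    series is judged against its own, shorter window.
    """
    thr = thresholds or QCThresholds()
    mask = brain_mask if brain_mask is not None else np.ones(series.shape, bool)
    n_base = n_baseline or estimate_baseline_frames(series, mask)
    conc = baseline_subtract(series, n_base)
    curve = mean_bolus_curve(conc, mask)

    window = series.duration
    peak_idx = int(np.argmax(curve))
    peak_height = float(curve[peak_idx])
    peak_fraction = (peak_idx * series.dt) / window if window > 0 else 1.0

    mi = motion_index(series, mask)
    finite = mi[np.isfinite(mi)]
    min_mi = float(finite.min()) if finite.size else np.nan
    zero_variance = not np.all(np.isfinite(mi))

    flags = {
        "truncated_bolus": peak_fraction > thr.peak_position_max,
        "low_cnr": peak_height < thr.peak_height_min_hu,
        "motion": zero_variance or min_mi < thr.motion_index_min,
    }
    bolus_flat = float(np.ptp(curve)) <= 0.0
    uninterpretable = bolus_flat or zero_variance or (
        np.isfinite(min_mi) and min_mi < thr.motion_index_fatal)
    quality = "high" if not any(flags.values()) else "impaired"
    return QCReport(peak_fraction, peak_height, mi, min_mi, flags, quality,
                    uninterpretable, thr)
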