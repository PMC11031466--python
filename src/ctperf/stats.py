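"""Agreement statistics between reference and subsampled measurements.

The agreement between paired volume measurements (reference sampling vs a
coarser one) is quantified with the two-way random-effects, absolute-
agreement, single-measure intraclass correlation ICC(2,1), plus the median
and standard deviation of the paired differences and Bland-Altman pairs.
The median is preferred over the mean because volume differences are
typically heavy-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgreementResult", "icc", "difference_stats", "cohort_agreement"]


@dataclass
class AgreementResult:
    """Agreement between a reference and a test measurement series."""

    icc: float
    median_diff: float        # median(test - reference)
    sd_diff: float            # SD of (test - reference), ddof=1
    n: int
    bland_altman: np.ndarray  # (n, 2): mean, difference

    def to_dict(self) -> dict:
        return {"icc": self.icc, "median_diff": self.median_diff,
                "sd_diff": self.sd_diff, "n": self.n}


def icc(reference: np.ndarray, test: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the classical mean-squares decomposition of the n x 2 table with
    subjects as rows and the two measurements as columns:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the total variance is zero (all values identical);
    identical non-constant vectors give exactly 1.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reference and test must be paired 1D arrays")
    if x.size < 2:
        raise ValueError("ICC requires at least 2 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ICC requires finite values")
    table = np.column_stack([x, y])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_total = ((table - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        return np.nan
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def difference_stats(reference: np.ndarray, test: np.ndarray) -> AgreementResult:
    """Median/SD of (test - reference) plus Bland-Altman pairs and ICC."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("reference and test must be paired")
    diff = y - x
    ba = np.column_stack([(x + y) / 2.0, diff])
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    icc_val = icc(x, y) if x.size >= 2 else np.nan
    return AgreementResult(icc_val, float(np.median(diff)), sd, int(x.size), ba)


def cohort_agreement(volumes: pd.DataFrame,
                     metrics: tuple[str, ...] = ("core_volume", "hypoperfusion_volume",
                                                 "mismatch_volume", "mismatch_ratio"),
                     reference_factor: int = 1) -> pd.DataFrame:
    """Per-stratum agreement tables from a long-format cohort result frame.

    ``volumes`` needs one row per (case_id, factor) with columns
    ``case_id``, ``factor``, ``quality_class`` (at the reference sampling),
    the metric columns and ``ratio_evaluable``. For every quality stratum,
    metric and non-reference factor this computes ICC(2,1), median and SD
    of the differences versus the reference. Mismatch-ratio rows are
    restricted to cases whose core volume exceeds the evaluability floor at
    both samplings; strata with fewer than 2 cases are skipped.
    """
    required = {"case_id", "factor", "quality_class"}
    if not required <= set(volumes.columns):
        raise ValueError(f"volumes frame must contain columns {sorted(required)}")
    rows = []
    ref = volumes[volumes["factor"] == reference_factor].set_index("case_id")
    strata = [("high",), ("impaired",), ("high", "impaired")]
    for stratum in strata:
        name = "all" if len(stratum) > 1 else stratum[0]
        ref_s = ref[ref["quality_class"].isin(stratum)]
        for factor in sorted(volumes["factor"].unique()):
            if factor == reference_factor:
                continue
            test = volumes[(volumes["factor"] == factor)
                           & volumes["case_id"].isin(ref_s.index)].set_index("case_id")
            test = test.loc[test.index.intersection(ref_s.index)]
            for metric in metrics:
                r = ref_s.loc[test.index, metric].to_numpy(dtype=float)
                t = test[metric].to_numpy(dtype=float)
                if metric == "mismatch_ratio":
                    keep = (ref_s.loc[test.index, "ratio_evaluable"].to_numpy(bool)
                            & test["ratio_evaluable"].to_numpy(bool))
                    r, t = r[keep], t[keep]
                keep = np.isfinite(r) & np.isfinite(t)
                r, t = r[keep], t[keep]
                if r.size < 2:
                    continue
                res = difference_stats(r, t)
                rows.append({"stratum": name, "metric": metric, "factor": int(factor),
                             "icc": res.icc, "median_diff": res.median_diff,
                             "sd_diff": res.sd_diff, "n": res.n})
    return pd.DataFrame(rows)


def bland_altman_plot(result: AgreementResult, ax=None, label: str | None = None):
    """Render the Bland-Altman scatter with median and limits of agreement.

    Requires matplotlib (an optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean, diff = result.bland_altman[:, 0], result.bland_altman[:, 1]
    ax.scatter(mean, diff, s=12, alpha=0.6)
    ax.axhline(result.median_diff, color="k", lw=1)
    for lim in (result.median_diff - 1.96 * result.sd_diff,
                result.median_diff + 1.96 * result.sd_diff):
        ax.axhline(lim, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of measurements (mL)")
    ax.set_ylabel("test - reference (mL)")
    if label:
        ax.set_title(label)
    return ax
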