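"""Temporal subsampling of dynamic series by frame decimation.

Reduced temporal resolution is simulated by leaving out time points: a
factor-f scheme keeps frames 0, f, 2f, ... of the original acquisition, so
the effective sampling interval becomes f times the base interval. The
series always starts at the first acquired frame; it does not necessarily
end on the last one (the retained count is ceil(n / f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DynamicSeries

__all__ = ["SamplingScheme", "decimate"]


@dataclass(frozen=True)
class SamplingScheme:
    """A frame-decimation scheme: keep every ``factor``-th frame from 0."""

    factor: int
    base_dt: float
    n_frames: int

    def __post_init__(self) -> None:
        _validate_factor(self.factor)

    @property
    def effective_dt(self) -> float:
        return self.factor * self.base_dt

    @property
    def retained_indices(self) -> np.ndarray:
        return np.arange(0, self.n_frames, self.factor)

    @property
    def n_retained(self) -> int:
        return int(np.ceil(self.n_frames / self.factor))


def _validate_factor(factor) -> int:
    if isinstance(factor, bool) or not isinstance(factor, (int, np.integer)):
        raise ValueError(f"subsampling factor must be an integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"subsampling factor must be >= 1, got {factor}")
    return int(factor)


def decimate(series: DynamicSeries, factor: int) -> DynamicSeries:
    """Return the series retaining frames 0, factor, 2*factor, ...

    The new sampling interval is ``factor * series.dt`` and the retained
    frame count is ``ceil(n / factor)``. Factor 1 returns an identical
    (bit-exact) copy.
    """
    f = _validate_factor(factor)
    scheme = SamplingScheme(f, series.dt, series.n_frames)
    meta = dict(series.meta)
    meta["subsampling_factor"] = f * meta.get("subsampling_factor", 1)
    return DynamicSeries(
        series.data[scheme.retained_indices].copy(),
        scheme.effective_dt,
        series.voxel_size_mm,
        meta=meta,
    )
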