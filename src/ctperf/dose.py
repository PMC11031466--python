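"""Radiation-dose bookkeeping for temporally subsampled CT perfusion.

Frame decimation reduces dose in proportion to the retained frame count:
a factor-f scheme keeps ceil(n/f) of n frames, so CTDIvol, DLP and
effective dose all scale by ceil(n/f)/n relative to the reference
protocol. The two shipped reference protocols are the Siemens Somatom
Definition Flash (27 frames, CTDIvol 210 mGy) and Somatom Definition 64 AS
(30 frames, 259 mGy) brain-perfusion protocols at 80 kV / 180 mAs and
1.5 s sampling, alongside static NCCT and CTA rows of a multimodal stroke
work-up for comparison.

Scaled CTDIvol and DLP are rounded to integers and effective dose to two
decimals, as dose reports conventionally print them. The AS protocol at
factor 2 lands exactly on a .5 boundary (259 * 15/30 = 129.5), so its
printed value depends on the rounding convention; the rounding mode is
therefore configurable (banker's rounding by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = ["DoseProtocol", "StaticAcquisition", "scale_dose", "dose_table",
           "FLASH", "DEFINITION_AS", "NCCT", "CTA_HEAD_NECK",
           "load_protocols"]


@dataclass(frozen=True)
class DoseProtocol:
    """A dynamic CTP acquisition protocol with its dose figures."""

    name: str
    kv: float
    mas: float
    n_frames: int
    dt_s: float
    z_coverage_mm: float
    ctdi_vol_mgy: float
    dlp_mgy_cm: float
    effective_dose_msv: float

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.ctdi_vol_mgy, self.dlp_mgy_cm, self.effective_dose_msv) <= 0:
            raise ValueError("dose quantities must be positive")


@dataclass(frozen=True)
class StaticAcquisition:
    """A single-pass acquisition (NCCT, CTA) shown for dose comparison."""

    name: str
    z_coverage_mm: float
    ctdi_vol_mgy: float
    dlp_mgy_cm: float
    effective_dose_msv: float


FLASH = DoseProtocol("Somatom Definition Flash", kv=80, mas=180, n_frames=27,
                     dt_s=1.5, z_coverage_mm=100, ctdi_vol_mgy=210,
                     dlp_mgy_cm=2103, effective_dose_msv=4.61)
DEFINITION_AS = DoseProtocol("Somatom Definition 64 AS", kv=80, mas=180,
                             n_frames=30, dt_s=1.5, z_coverage_mm=90,
                             ctdi_vol_mgy=259, dlp_mgy_cm=2331,
                             effective_dose_msv=5.11)
NCCT = StaticAcquisition("NCCT", 160, 45, 724, 1.59)
CTA_HEAD_NECK = StaticAcquisition("CTA", 320, 6.5, 207, 1.13)


def _round(x: float, mode: str) -> int:
    if mode == "half_even":
        return int(round(x))
    if mode == "half_up":
        return int(math.floor(x + 0.5))
    if mode == "half_down":
        return int(math.ceil(x - 0.5))
    raise ValueError(f"unknown rounding mode {mode!r}")


def scale_dose(protocol: DoseProtocol, factor: int,
               rounding: str = "half_even") -> DoseProtocol:
    """Dose figures of the protocol under factor-f frame decimation.

    The retained frame count is ceil(n/f); every dose quantity scales by
    the retained proportion. CTDIvol and DLP are rounded to whole mGy /
    mGy*cm, effective dose to 2 decimals. Factor 1 returns the protocol
    unchanged.
    """
    if factor not in (1, 2, 3, 4):
        raise ValueError(f"subsampling factor must be 1-4, got {factor}")
    if factor == 1:
        return protocol
    n_sub = math.ceil(protocol.n_frames / factor)
    prop = n_sub / protocol.n_frames
    return replace(
        protocol,
        name=f"{protocol.name} ({protocol.dt_s * factor:g} s)",
        n_frames=n_sub,
        dt_s=protocol.dt_s * factor,
        ctdi_vol_mgy=_round(protocol.ctdi_vol_mgy * prop, rounding),
        dlp_mgy_cm=_round(protocol.dlp_mgy_cm * prop, rounding),
        effective_dose_msv=round(protocol.effective_dose_msv * prop, 2),
    )


def dose_table(protocols: Sequence[DoseProtocol] = (FLASH, DEFINITION_AS),
               factors: Iterable[int] = (1, 2, 3, 4),
               static: Sequence[StaticAcquisition] = (NCCT, CTA_HEAD_NECK),
               rounding: str = "half_even") -> pd.DataFrame:
    """Per-protocol, per-factor dose summary in the conventional layout.

    One row per acquisition: the static reference scans first, then every
    CTP protocol at every subsampling factor, with frame counts, sampling
    interval and the three scaled dose quantities.
    """
    rows = []
    for s in static:
        rows.append({"protocol": s.name, "factor": None, "sampling_interval_s": None,
                     "n_frames": None, "z_coverage_mm": s.z_coverage_mm,
                     "ctdi_vol_mgy": s.ctdi_vol_mgy, "dlp_mgy_cm": s.dlp_mgy_cm,
                     "effective_dose_msv": s.effective_dose_msv})
    for p in protocols:
        for f in factors:
            sp = scale_dose(p, f, rounding)
            rows.append({"protocol": p.name, "factor": f,
                         "sampling_interval_s": sp.dt_s, "n_frames": sp.n_frames,
                         "z_coverage_mm": sp.z_coverage_mm,
                         "ctdi_vol_mgy": sp.ctdi_vol_mgy, "dlp_mgy_cm": sp.dlp_mgy_cm,
                         "effective_dose_msv": sp.effective_dose_msv})
    return pd.DataFrame(rows)


def load_protocols(path) -> list[DoseProtocol]:
    """Read CTP dose protocols from a YAML file (list of mappings whose
    keys match the DoseProtocol fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [DoseProtocol(**entry) for entry in raw]
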