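"""End-to-end experiment orchestration.

Simulates a cohort of dynamic acquisitions, processes every case at the
reference sampling and at decimated samplings (3.0 / 4.5 / 6.0 s from a
1.5 s base), runs quality control, segments and measures lesions, applies
the DEFUSE-3 criteria, and aggregates agreement statistics, confusion
matrices and the radiation-dose table into one report bundle. Every
number in the bundle is produced by a module operation; this module only
wires them together and keeps the bookkeeping (reference-based exclusion,
per-case seeds, run manifest) deterministic under the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (CohortCase, DynamicSeries, PhantomCase, PhantomSpec,
                      build_phantom, cohort_generate, cohort_table)
from .sampling import decimate
from .perfusion import (DeconvConfig, PerfusionMaps, brain_mask_from_series,
                        compute_maps, correct_motion, motion_index)
from .qc import QCReport, QCThresholds, evaluate_qc
from .lesion import (ConfusionMatrix, Defuse3Decision, Defuse3Thresholds,
                     LesionReport, SegmentationThresholds, compare_decisions,
                     defuse3_decide, segment, volumetry)
from .stats import cohort_agreement
from .dose import dose_table

log = logging.getLogger("ctperf")

__all__ = ["RunConfig", "CaseResult", "ExperimentResult", "process_series",
           "run_case", "run_experiment", "pooled_clean_agreement"]


@dataclass
class RunConfig:
    """Everything a full experiment needs, serialised into the manifest.

    Thresholds default to the established clinical values: Tmax > 6 s,
    CBF < 30%, 3 mL ratio floor, DEFUSE-3 70 mL / 15 mL / 1.8 with
    5 mL / 0.2 margins, and the QC cut-offs (90% window, 8 HU, 0.7).
    """

    n_subjects: int = 50
    factors: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    segmentation: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    defuse3: Defuse3Thresholds = field(default_factory=Defuse3Thresholds)
    qc: QCThresholds = field(default_factory=QCThresholds)
    scenario_probs: dict | None = None
    #: realign frames to frame 0 when the minimum motion index falls below
    #: this value (0 disables, 1 always realigns)
    motion_correct_below: float = 0.9
    output_dir: str | None = None

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["phantom"]["aif"] = dataclasses.asdict(self.phantom.aif)
        out["package_version"] = __version__
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        plain = {f.name: f.type for f in dataclasses.fields(cls)}
        builders = {"phantom": PhantomSpec, "deconv": DeconvConfig,
                    "segmentation": SegmentationThresholds,
                    "defuse3": Defuse3Thresholds, "qc": QCThresholds}
        for key, value in raw.items():
            if key not in plain:
                raise ValueError(f"unknown config key {key!r}")
            if key in builders and isinstance(value, dict):
                kwargs[key] = builders[key](**value)
            elif key == "factors":
                kwargs[key] = tuple(int(v) for v in value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class CaseResult:
    """Everything measured for one case at one sampling."""

    case_id: int
    factor: int
    qc: QCReport
    lesion: LesionReport
    decision: Defuse3Decision
    maps: PerfusionMaps | None = None


def process_series(series: DynamicSeries, config: RunConfig,
                   brain_mask: np.ndarray | None = None,
                   keep_maps: bool = False) -> tuple[QCReport, LesionReport,
                                                     Defuse3Decision,
                                                     PerfusionMaps | None]:
    """QC, optional motion correction, maps, segmentation and decision for
    one (possibly decimated) series."""
    if brain_mask is None:
        brain_mask = brain_mask_from_series(series)
    qc_report = evaluate_qc(series, brain_mask, config.qc)
    if (config.motion_correct_below > 0
            and qc_report.min_motion_index < config.motion_correct_below):
        series, shifts = correct_motion(series, brain_mask)
        log.debug("motion correction applied, max shift %s",
                  np.abs(shifts).max(axis=0).tolist())
    maps = compute_maps(series, cfg=config.deconv, brain_mask=brain_mask)
    hypo, core = segment(maps, config.segmentation)
    report = volumetry(hypo, core, maps.voxel_volume_ml,
                       config.segmentation.core_evaluable_ml)
    decision = defuse3_decide(report, config.defuse3)
    return qc_report, report, decision, (maps if keep_maps else None)


def run_case(case: CohortCase | PhantomCase, config: RunConfig,
             keep_maps: bool = False) -> dict[int, CaseResult]:
    """Process one phantom case at every configured sampling factor.

    The factor-1 result is the reference; coarser samplings are obtained
    by frame decimation of the same acquisition.
    """
    if isinstance(case, CohortCase):
        case_id, built = case.case_id, case.build()
    else:
        case_id, built = case.seed, case
    out: dict[int, CaseResult] = {}
    for f in config.factors:
        sub = decimate(built.series, f)
        qc_report, report, decision, maps = process_series(
            sub, config, brain_mask=built.masks.get("brain"), keep_maps=keep_maps)
        out[f] = CaseResult(case_id, f, qc_report, report, decision, maps)
    return out


@dataclass
class ExperimentResult:
    """The report bundle of one full experiment."""

    volumes: pd.DataFrame           # one row per (case, factor)
    agreement: pd.DataFrame         # ICC / median / SD per stratum-metric-factor
    confusion: dict[int, ConfusionMatrix]
    dose: pd.DataFrame
    qc_summary: pd.DataFrame
    cohort: pd.DataFrame            # ground-truth design table
    excluded: list[dict]
    manifest: dict

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.volumes.to_csv(out / "volumes.csv", index=False)
        self.agreement.to_csv(out / "agreement.csv", index=False)
        self.dose.to_csv(out / "dose_table.csv", index=False)
        self.qc_summary.to_csv(out / "qc_summary.csv", index=False)
        self.cohort.to_csv(out / "cohort_ground_truth.csv", index=False)
        for f, cm in self.confusion.items():
            cm.to_frame().to_csv(out / f"confusion_factor{f}.csv")
        payload = {"manifest": self.manifest, "excluded": self.excluded,
                   "confusion": {str(f): dataclasses.asdict(cm)
                                 for f, cm in self.confusion.items()}}
        (out / "manifest.json").write_text(json.dumps(payload, indent=2) + "\n")


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Simulate, process and analyse a whole cohort deterministically.

    Cases whose reference-sampling QC is uninterpretable are excluded from
    the agreement and decision analyses and listed in the exclusion log,
    mirroring how fatally corrupted scans are removed before analysis.
    """
    if config.n_subjects < 1:
        raise ValueError("empty cohort")
    cases = cohort_generate(config.n_subjects, config.seed,
                            base_spec=config.phantom,
                            scenario_probs=config.scenario_probs)
    ref_factor = config.factors[0]
    vol_rows, qc_rows, excluded = [], [], []
    decisions: dict[int, dict[int, Defuse3Decision]] = {f: {} for f in config.factors}
    for case in cases:
        results = run_case(case, config)
        ref = results[ref_factor]
        if ref.qc.uninterpretable:
            excluded.append({"case_id": case.case_id,
                             "reason": "uninterpretable at reference sampling",
                             "flags": [k for k, v in ref.qc.flags.items() if v]})
            log.info("case %d excluded at reference QC", case.case_id)
            continue
        for f, res in results.items():
            vol_rows.append({
                "case_id": case.case_id, "factor": f,
                "scenario": case.spec.scenario,
                "quality_class": ref.qc.quality_class,
                "core_volume": res.lesion.core_volume,
                "hypoperfusion_volume": res.lesion.hypoperfusion_volume,
                "mismatch_volume": res.lesion.mismatch_volume,
                "mismatch_ratio": res.lesion.mismatch_ratio,
                "ratio_evaluable": res.lesion.ratio_evaluable,
                "decision": res.decision.eligible,
                "in_margin_zone": res.decision.in_margin_zone,
            })
            qc_rows.append({"case_id": case.case_id, "factor": f,
                            "quality_class": res.qc.quality_class,
                            "uninterpretable": res.qc.uninterpretable,
                            "peak_height_hu": res.qc.peak_height_hu,
                            "peak_position_fraction": res.qc.peak_position_fraction,
                            "min_motion_index": res.qc.min_motion_index,
                            **{f"flag_{k}": v for k, v in res.qc.flags.items()}})
            decisions[f][case.case_id] = res.decision

    volumes = pd.DataFrame(vol_rows)
    if volumes.empty:
        raise ValueError("all cases excluded; nothing to analyse")
    agreement = cohort_agreement(volumes, reference_factor=ref_factor)
    kept = sorted(decisions[ref_factor])
    confusion = {f: compare_decisions([decisions[ref_factor][i] for i in kept],
                                      [decisions[f][i] for i in kept])
                 for f in config.factors if f != ref_factor}
    result = ExperimentResult(
        volumes=volumes,
        agreement=agreement,
        confusion=confusion,
        dose=dose_table(factors=config.factors),
        qc_summary=pd.DataFrame(qc_rows),
        cohort=cohort_table(cases),
        excluded=excluded,
        manifest=config.to_manifest(),
    )
    if config.output_dir:
        result.save(config.output_dir)
    return result


def pooled_clean_agreement(base_seed: int, n_replicates: int = 6,
                           n_subjects: int = 50,
                           config: RunConfig | None = None):
    """Reference-vs-subsampled agreement pooled over replicate clean cohorts.

    The sampling-robustness question is answered on clean-quality cohorts:
    each replicate simulates ``n_subjects`` clean cases under its own seed
    (base_seed, base_seed+1, ...), processes them at every factor, and the
    paired volume differences from all replicates are pooled before
    computing ICC, median and SD. Pooling controls the sampling noise of
    the SD estimates, which on a single cohort is of the same order as the
    difference between adjacent factors. Returns (agreement frame,
    discordance frame).
    """
    base = config if config is not None else RunConfig()
    metrics = {"core_volume": "core", "hypoperfusion_volume": "hypoperfusion"}
    pairs: dict[tuple[str, int], list[np.ndarray]] = {}
    disc_rows = {f: {"n_discordant": 0, "n_counted": 0, "n_excluded_margin": 0}
                 for f in base.factors if f != base.factors[0]}
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, n_subjects=n_subjects,
                                  seed=int(base_seed) + rep,
                                  scenario_probs={"clean": 1.0},
                                  output_dir=None)
        result = run_experiment(cfg)
        ref_factor = cfg.factors[0]
        piv = {m: result.volumes.pivot(index="case_id", columns="factor", values=m)
               for m in metrics}
        for m in metrics:
            for f in cfg.factors:
                if f == ref_factor:
                    continue
                both = piv[m][[ref_factor, f]].dropna()
                pairs.setdefault((m, f), []).append(both.to_numpy())
        for f, cm in result.confusion.items():
            disc_rows[f]["n_discordant"] += cm.n_discordant
            disc_rows[f]["n_counted"] += cm.n_counted
            disc_rows[f]["n_excluded_margin"] += cm.n_excluded_margin

    from .stats import difference_stats

    rows = []
    for (m, f), chunks in sorted(pairs.items()):
        table = np.vstack(chunks)
        res = difference_stats(table[:, 0], table[:, 1])
        rows.append({"metric": metrics[m], "factor": f, "icc": res.icc,
                     "median_diff": res.median_diff, "sd_diff": res.sd_diff,
                     "n": res.n})
    disc = pd.DataFrame([{"factor": f, **row,
                          "discordance_rate": row["n_discordant"] / row["n_counted"]
                          if row["n_counted"] else np.nan}
                         for f, row in sorted(disc_rows.items())])
    return pd.DataFrame(rows), disc
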