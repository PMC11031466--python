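"""Synthetic 4D CT-perfusion phantom with known ground-truth hemodynamics.

Generates dynamic contrast-enhanced CT series of a two-hemisphere brain slab:
a gamma-variate arterial bolus drives per-voxel tissue enhancement through an
indicator-dilution forward model (flow-scaled residue-function convolution).
Ischemic lesions are ellipsoidal regions with reduced relative CBF and delayed
bolus arrival, always confined to the left hemisphere (x below the midline).
Three artifact scenarios reproduce the failure modes automated quality control
must catch: a bolus peaking too late in the acquisition window, a bolus too
weak relative to noise, and rigid in-plane patient motion.

All randomness is driven by an explicit seed; the same seed yields a
bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GammaVariateParams",
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "DynamicSeries",
    "PhantomCase",
    "CohortCase",
    "gamma_variate",
    "tissue_curve",
    "build_phantom",
    "cohort_generate",
    "cohort_table",
]

#: Reference mean transit time (s) used to express relative CBV as
#: cbv_rel = cbf_rel * mtt / MTT_REFERENCE_S (central-volume theorem).
MTT_REFERENCE_S = 4.0

SCENARIOS = ("clean", "low_cnr", "late_bolus", "motion")


# ---------------------------------------------------------------------------
# Bolus and tissue forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaVariateParams:
    """Gamma-variate bolus: c(t) = A ((t-t0)/(ab))^a exp(a - (t-t0)/b).

    Normalised so the curve peaks at ``amplitude`` at t = t0 + alpha*beta.
    """

    t0: float          # bolus arrival time (s)
    alpha: float       # shape exponent, > 0
    beta: float        # time scale (s), > 0
    amplitude: float   # peak height (HU above baseline)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"gamma-variate requires alpha > 0 and beta > 0, "
                f"got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def t_peak(self) -> float:
        """Analytic maximiser t0 + alpha*beta (s)."""
        return self.t0 + self.alpha * self.beta


def gamma_variate(t: np.ndarray, params: GammaVariateParams) -> np.ndarray:
    """Evaluate a gamma-variate bolus on time grid ``t`` (s).

    Zero for t <= t0, non-negative, single interior maximum equal to
    ``params.amplitude`` at ``params.t_peak``.
    """
    t = np.asarray(t, dtype=float)
    tau = (t - params.t0) / (params.alpha * params.beta)
    out = np.zeros_like(t)
    pos = tau > 0
    out[pos] = params.amplitude * tau[pos] ** params.alpha * np.exp(
        params.alpha * (1.0 - tau[pos])
    )
    return out


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth hemodynamic state of a tissue class.

    cbf_rel is the flow as a fraction of normal tissue (1.0 = normal);
    mtt is the mean transit time (s); delay is the bolus arrival delay
    relative to the arterial input (s, 0 for normal tissue).
    """

    cbf_rel: float
    mtt: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.mtt <= 0:
            raise ValueError(f"mtt must be > 0, got {self.mtt}")
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")
        if self.cbf_rel < 0:
            raise ValueError(f"cbf_rel must be >= 0, got {self.cbf_rel}")

    @property
    def cbv_rel(self) -> float:
        """Implied relative CBV via the central-volume theorem."""
        return self.cbf_rel * self.mtt / MTT_REFERENCE_S


def _residue(t: np.ndarray, mtt: float, model: str) -> np.ndarray:
    if model == "exponential":
        return np.exp(-t / mtt)
    if model == "boxcar":
        return (t < mtt).astype(float)
    raise ValueError(f"unknown residue model {model!r}")


def tissue_curve(
    aif: np.ndarray,
    params: TissueParams,
    dt: float,
    residue: str = "exponential",
) -> np.ndarray:
    """Tissue concentration from an arterial input via indicator dilution.

    c_tissue(t) = cbf_rel * (aif(. - delay) * R)(t) * dt with residue
    R(t) = exp(-t/mtt) (or a boxcar of width mtt). The AIF must be sampled
    on a uniform grid with spacing ``dt``; the delay shift uses linear
    interpolation so it need not be a grid multiple.
    """
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    t = np.arange(n) * dt
    if params.delay > 0:
        aif = np.interp(t - params.delay, t, aif, left=0.0, right=aif[-1])
    r = _residue(t, params.mtt, residue)
    return params.cbf_rel * np.convolve(aif, r)[:n] * dt


# ---------------------------------------------------------------------------
# Phantom geometry and acquisition spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal ischemic lesion: a hypoperfused penumbra shell with an
    infarct core nested inside it (same centre, smaller radii).

    Coordinates and radii are in millimetres, in (z, y, x) order.
    """

    center_mm: tuple[float, float, float]
    penumbra_radii_mm: tuple[float, float, float]
    core_radii_mm: tuple[float, float, float]
    penumbra: TissueParams = TissueParams(cbf_rel=0.55, mtt=6.0, delay=9.0)
    core: TissueParams = TissueParams(cbf_rel=0.15, mtt=8.0, delay=10.5)
    #: fraction of the penumbra radius over which delay/CBF/MTT taper
    #: linearly back to normal (the hypoperfused region shades into
    #: oligemic tissue rather than ending abruptly)
    edge_ramp_frac: float = 0.06

    def __post_init__(self) -> None:
        if any(c > p + 1e-9 for c, p in zip(self.core_radii_mm, self.penumbra_radii_mm)):
            raise ValueError("core radii must not exceed penumbra radii (nesting)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition and scenario parameters of one synthetic case."""

    shape: tuple[int, int, int] = (8, 80, 80)          # (z, y, x) voxels
    voxel_size_mm: tuple[float, float, float] = (5.0, 2.0, 2.0)
    n_frames: int = 27
    dt: float = 1.5                                     # sampling interval (s)
    baseline_hu: float = 35.0
    noise_sigma: float = 2.0                            # HU
    structure_sigma_hu: float = 12.0                    # static anatomy texture
    structure_smooth_vox: float = 2.0                   # in-plane smoothing
    aif: GammaVariateParams = GammaVariateParams(t0=8.0, alpha=3.0, beta=1.5, amplitude=9.0)
    arterial_amplitude_hu: float = 140.0                # displayed artery peak
    normal: TissueParams = TissueParams(cbf_rel=1.0, mtt=4.0, delay=0.0)
    lesion: LesionSpec | None = None
    scenario: str = "clean"
    residue_model: str = "exponential"
    low_cnr_peak_hu: float = 5.0                        # target mean-brain peak
    motion_shift_vox: tuple[int, int] = (2, 2)          # (dy, dx)
    motion_frames: tuple[int, int] = (12, 19)           # [start, stop) frames
    dt_sim: float = 0.1                                 # dense forward-model grid

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_frames < 2 or self.dt <= 0:
            raise ValueError("need n_frames >= 2 and dt > 0")

    @property
    def duration(self) -> float:
        """Acquisition window n_frames * dt (s)."""
        return self.n_frames * self.dt

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class DynamicSeries:
    """A 4D dynamic CT acquisition: HU data on a uniform time grid.

    data has axes (t, z, y, x); the hemisphere convention is a left/right
    split along the x midline (left = lower x indices).
    """

    data: np.ndarray
    dt: float
    voxel_size_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries.data must be 4D (t, z, y, x)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DynamicSeries.data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        """Acquisition window (n_frames - 1) * dt (s)."""
        return (self.n_frames - 1) * self.dt

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def _elliptical_radius(
    shape: tuple[int, int, int],
    voxel_size_mm: Sequence[float],
    center_mm: Sequence[float],
    radii_mm: Sequence[float],
) -> np.ndarray:
    """Normalised elliptical radius of each voxel centre (1 on the surface).

    Degenerate (zero) radii yield +inf everywhere, i.e. an empty ellipsoid.
    """
    if min(radii_mm) <= 0:
        return np.full(shape, np.inf)
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size_mm)],
        indexing="ij",
    )
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return np.sqrt(d2)


def _ellipsoid_mask(shape, voxel_size_mm, center_mm, radii_mm) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the ellipsoid."""
    return _elliptical_radius(shape, voxel_size_mm, center_mm, radii_mm) <= 1.0


def _validate_lesion(spec: PhantomSpec) -> None:
    if spec.lesion is None:
        return
    les = spec.lesion
    extent = [n * v for n, v in zip(spec.shape, spec.voxel_size_mm)]
    midline_mm = extent[2] / 2.0
    for c, r, hi in zip(les.center_mm, les.penumbra_radii_mm, extent):
        if c - r < -1e-9 or c + r > hi + 1e-9:
            raise ValueError("lesion extends outside the grid")
    if les.center_mm[2] + les.penumbra_radii_mm[2] > midline_mm + 1e-9:
        raise ValueError("lesion must be confined to the left hemisphere")


#: Number of quantisation levels of the lesion edge ramp; severity within a
#: lesion is piecewise constant over these bands so each band shares one
#: forward-model curve.
_N_EDGE_BANDS = 8

#: Delay (s) above which tissue counts as hypoperfused in the ground truth,
#: matching the Tmax > 6 s operational definition.
HYPOPERFUSION_DELAY_S = 6.0


def _severity_weight(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel lesion severity in [0, 1], banded.

    1 deep inside the penumbra ellipsoid, tapering linearly to 0 over the
    outer ``edge_ramp_frac`` of its radius, quantised to _N_EDGE_BANDS
    levels so voxels group into a small number of tissue classes.
    """
    if spec.lesion is None:
        return np.zeros(spec.shape)
    les = spec.lesion
    re = _elliptical_radius(spec.shape, spec.voxel_size_mm, les.center_mm,
                            les.penumbra_radii_mm)
    ramp = max(les.edge_ramp_frac, 1e-6)
    w = np.clip((1.0 - re) / ramp, 0.0, 1.0)
    return np.ceil(w * _N_EDGE_BANDS) / _N_EDGE_BANDS


def _artery_mask(spec: PhantomSpec) -> np.ndarray:
    """Small arterial blob near the anterior midline of the left hemisphere."""
    extent = [n * v for n, v in zip(spec.shape, spec.voxel_size_mm)]
    center = (extent[0] / 2.0, 12.0, extent[2] / 2.0 - 10.0)
    return _ellipsoid_mask(spec.shape, spec.voxel_size_mm, center, (5.0, 5.0, 5.0))


@dataclass
class PhantomCase:
    """A built phantom: the series plus voxelwise ground truth."""

    series: DynamicSeries
    cbf_map: np.ndarray       # relative CBF fraction (nan in artery)
    mtt_map: np.ndarray       # s
    delay_map: np.ndarray     # s
    cbv_map: np.ndarray       # relative CBV fraction
    masks: dict[str, np.ndarray]
    spec: PhantomSpec
    seed: int

    @property
    def voxel_volume_ml(self) -> float:
        return self.spec.voxel_volume_ml

    def mask_volume_ml(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_ml


def _class_curves(spec: PhantomSpec, aif_params: GammaVariateParams,
                  classes: dict[str, TissueParams]) -> dict[str, np.ndarray]:
    """Noiseless enhancement curves at the frame times, per tissue class.

    Curves are simulated on a dense grid (dt_sim) so the acquisition grid
    genuinely samples a continuous process, then linearly interpolated at
    the frame times.
    """
    t_dense = np.arange(0.0, (spec.n_frames - 1) * spec.dt + spec.dt_sim, spec.dt_sim)
    aif_dense = gamma_variate(t_dense, aif_params)
    t_frames = spec.frame_times
    out: dict[str, np.ndarray] = {}
    for name, params in classes.items():
        dense = tissue_curve(aif_dense, params, spec.dt_sim, spec.residue_model)
        out[name] = np.interp(t_frames, t_dense, dense)
    scale = spec.arterial_amplitude_hu / aif_params.amplitude if aif_params.amplitude else 0.0
    out["artery"] = np.interp(t_frames, t_dense, aif_dense) * scale
    return out


def build_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Build one synthetic acquisition with ground truth.

    Per voxel: baseline + static anatomy texture + class enhancement curve
    + white Gaussian noise. Scenario handling:

    - ``low_cnr``: enhancement globally rescaled so the noiseless mean-brain
      bolus peak equals ``low_cnr_peak_hu`` (below the 8 HU QC threshold).
    - ``late_bolus``: bolus arrival pushed to 80% of the acquisition window
      so the mean-brain curve is still rising at the last frame.
    - ``motion``: a contiguous frame block is rigidly shifted in-plane by
      ``motion_shift_vox`` (circular shift; the static anatomy texture makes
      the frame-0 correlation drop).
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    _validate_lesion(spec)
    artery = _artery_mask(spec)
    brain = np.ones(spec.shape, dtype=bool)

    aif_params = spec.aif
    if spec.scenario == "late_bolus":
        aif_params = replace(aif_params, t0=0.8 * spec.duration)

    # tissue classes: normal, core, and one class per lesion edge band
    les = spec.lesion
    severity = _severity_weight(spec)
    if les is not None:
        core_mask = _ellipsoid_mask(spec.shape, spec.voxel_size_mm,
                                    les.center_mm, les.core_radii_mm) & ~artery
    else:
        core_mask = np.zeros(spec.shape, dtype=bool)

    classes: dict[str, TissueParams] = {"normal": spec.normal}
    class_masks = {"normal": brain & ~artery & ~core_mask & (severity == 0),
                   "artery": artery}
    if les is not None:
        classes["core"] = les.core
        class_masks["core"] = core_mask
        normal_p, pen = spec.normal, les.penumbra
        for lvl in np.unique(severity[severity > 0]):
            name = f"band_{lvl:.3f}"
            classes[name] = TissueParams(
                cbf_rel=normal_p.cbf_rel + (pen.cbf_rel - normal_p.cbf_rel) * lvl,
                mtt=normal_p.mtt + (pen.mtt - normal_p.mtt) * lvl,
                delay=pen.delay * lvl,
            )
            class_masks[name] = (severity == lvl) & ~artery & ~core_mask

    curves = _class_curves(spec, aif_params, classes)
    if spec.scenario == "low_cnr":
        n_brain = brain.sum()
        mean_curve = sum(curves[c] * class_masks[c].sum() for c in curves) / n_brain
        peak = float(mean_curve.max())
        if peak > 0:
            factor = spec.low_cnr_peak_hu / peak
            curves = {c: v * factor for c, v in curves.items()}

    # static anatomy: smooth in-plane texture shared by all frames
    texture = rng.standard_normal(spec.shape)
    texture = gaussian_filter(texture, sigma=(0.5,) + (spec.structure_smooth_vox,) * 2)
    texture *= spec.structure_sigma_hu / max(texture.std(), 1e-12)
    static = spec.baseline_hu + texture

    data = np.empty((spec.n_frames, nz, ny, nx))
    for t in range(spec.n_frames):
        frame = static.copy()
        for cls, mask in class_masks.items():
            frame[mask] += curves[cls][t]
        data[t] = frame

    if spec.scenario == "motion":
        dy, dx = spec.motion_shift_vox
        lo, hi = spec.motion_frames
        hi = min(hi, spec.n_frames)
        for t in range(lo, hi):
            data[t] = np.roll(data[t], shift=(dy, dx), axis=(1, 2))

    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, data.shape)

    cbf = np.full(spec.shape, spec.normal.cbf_rel)
    mtt = np.full(spec.shape, spec.normal.mtt)
    delay = np.zeros(spec.shape)
    for name, params in classes.items():
        if name == "normal":
            continue
        m = class_masks[name]
        cbf[m], mtt[m], delay[m] = params.cbf_rel, params.mtt, params.delay
    cbf[artery] = np.nan
    mtt[artery] = np.nan
    cbv = cbf * mtt / MTT_REFERENCE_S

    hypo = delay > HYPOPERFUSION_DELAY_S
    series = DynamicSeries(
        data, spec.dt, spec.voxel_size_mm,
        meta={"seed": int(seed), "scenario": spec.scenario},
    )
    masks = {"brain": brain, "artery": artery, "hypoperfusion": hypo,
             "core": core_mask, "penumbra": hypo & ~core_mask}
    return PhantomCase(series, cbf, mtt, delay, cbv, masks, spec, int(seed))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCase:
    """One subject of a synthetic cohort: spec, per-case seed and targets."""

    case_id: int
    spec: PhantomSpec
    seed: int
    core_target_ml: float
    hypoperfusion_target_ml: float

    def build(self) -> PhantomCase:
        return build_phantom(self.spec, self.seed)


def _radii_for_volume(volume_ml: float, extent_mm: Sequence[float]) -> tuple[float, float, float]:
    """Ellipsoid radii (mm) of the requested volume fitting the slab.

    Prefers an isotropic shape, then caps the z radius by slab thickness and
    the x radius by hemisphere width, inflating the other axes to preserve
    volume.
    """
    if volume_ml <= 0:
        return (0.0, 0.0, 0.0)
    v_mm3 = volume_ml * 1000.0
    az_max = extent_mm[0] / 2.0 - 2.0
    ax_max = extent_mm[2] / 4.0 - 2.0   # lesion centred mid-hemisphere
    a_iso = (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    az = min(a_iso, az_max)
    ay = ax = np.sqrt(3.0 * v_mm3 / (4.0 * np.pi * az))
    if ax > ax_max:
        ax = ax_max
        ay = 3.0 * v_mm3 / (4.0 * np.pi * az * ax)
    return (float(az), float(ay), float(ax))


def cohort_generate(
    n_subjects: int,
    seed: int,
    *,
    base_spec: PhantomSpec | None = None,
    core_volume_range_ml: tuple[float, float] = (0.0, 110.0),
    mismatch_volume_range_ml: tuple[float, float] = (5.0, 100.0),
    p_no_lesion: float = 0.10,
    p_no_core: float = 0.12,
    scenario_probs: dict[str, float] | None = None,
) -> list[CohortCase]:
    """Sample a cohort of phantom cases with varied lesions and scenarios.

    Core-volume targets are drawn uniformly over ``core_volume_range_ml`` so
    the 70 mL DEFUSE-3 core threshold is straddled; a fraction of cases have
    no lesion at all and a fraction have hypoperfusion without core. The
    scenario mix defaults to 90% clean and the remainder split evenly over
    the three artifact classes. Fully deterministic under a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    if scenario_probs is None:
        scenario_probs = {"clean": 0.90, "low_cnr": 1.0 / 30, "late_bolus": 1.0 / 30,
                          "motion": 1.0 / 30}
    names = list(scenario_probs)
    probs = np.asarray([scenario_probs[k] for k in names], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    extent = [n * v for n, v in zip(base.shape, base.voxel_size_mm)]
    center = (extent[0] / 2.0, extent[1] / 2.0, extent[2] / 4.0)
    cases: list[CohortCase] = []
    for i in range(n_subjects):
        case_seed = int(rng.integers(0, 2**31 - 1))
        scenario = str(names[rng.choice(len(names), p=probs)])
        u = rng.random()
        if u < p_no_lesion:
            core_t, hypo_t, lesion = 0.0, 0.0, None
        else:
            if u < p_no_lesion + p_no_core:
                core_t = 0.0
            else:
                core_t = float(rng.uniform(*core_volume_range_ml))
            mismatch = float(rng.uniform(*mismatch_volume_range_ml))
            hypo_t = core_t + mismatch
            pen_delay = float(rng.uniform(6.2, 13.0))
            lesion = LesionSpec(
                center_mm=center,
                penumbra_radii_mm=_radii_for_volume(hypo_t, extent),
                core_radii_mm=_radii_for_volume(core_t, extent),
                penumbra=TissueParams(
                    cbf_rel=float(rng.uniform(0.45, 0.75)),
                    mtt=float(rng.uniform(5.0, 7.0)), delay=pen_delay),
                core=TissueParams(
                    cbf_rel=float(rng.uniform(0.08, 0.20)),
                    mtt=float(rng.uniform(7.0, 10.0)),
                    delay=pen_delay + float(rng.uniform(0.5, 2.5))),
            )
        # per-case circulation variability: bolus arrival time, strength
        # (injection quality / cardiac output) and width all vary patient
        # to patient; narrow boluses are the classic coarse-sampling hazard
        amp = float(rng.uniform(0.6, 1.4))
        aif = replace(base.aif, t0=float(rng.uniform(6.5, 9.5)),
                      beta=float(rng.uniform(1.2, 2.2)),
                      amplitude=base.aif.amplitude * amp)
        spec = replace(base, lesion=lesion, scenario=scenario, aif=aif,
                       arterial_amplitude_hu=base.arterial_amplitude_hu * amp)
        cases.append(CohortCase(i, spec, case_seed, core_t, hypo_t))
    return cases


def cohort_table(cases: Sequence[CohortCase]):
    """Ground-truth design table of a generated cohort (one row per case)."""
    import pandas as pd

    rows = []
    for c in cases:
        les = c.spec.lesion
        rows.append({
            "case_id": c.case_id,
            "seed": c.seed,
            "scenario": c.spec.scenario,
            "core_target_ml": c.core_target_ml,
            "hypoperfusion_target_ml": c.hypoperfusion_target_ml,
            "core_cbf_rel": les.core.cbf_rel if les else np.nan,
            "penumbra_cbf_rel": les.penumbra.cbf_rel if les else np.nan,
            "penumbra_delay_s": les.penumbra.delay if les else np.nan,
            "core_delay_s": les.core.delay if les else np.nan,
        })
    return pd.DataFrame(rows)
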