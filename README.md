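# ctperf

Brain CT-perfusion (CTP) simulation and analysis: how far can the
temporal sampling of a dynamic perfusion acquisition be coarsened —
cutting radiation dose in proportion — before perfusion maps, ischemic
volumes and thrombectomy decisions degrade?

The package is aimed at perfusion-imaging researchers and medical
physicists. It provides, as composable library modules and a thin CLI:

- **`ctperf.phantom`** — a synthetic 4D brain-perfusion phantom cohort
  with known ground truth: gamma-variate arterial boluses, indicator-
  dilution tissue curves over a two-hemisphere slab, ischemic lesions
  with reduced relative CBF and delayed arrival, and the three artifact
  classes automated QC must catch (late/truncated bolus, low
  contrast-to-noise, patient motion).
- **`ctperf.sampling`** — temporal subsampling by frame decimation
  (keep frames 0, f, 2f, ...; 1.5 s → 3.0/4.5/6.0 s).
- **`ctperf.perfusion`** — Tikhonov-regularised deconvolution on a
  delay-preserving circulant embedding, producing CBF, CBV (percent of
  the contralateral hemisphere), Tmax and MTT maps, with automatic AIF
  selection and rigid motion correction.
- **`ctperf.qc`** — the automated quality rules: bolus peak later than
  90% of the window, peak below 8 HU, motion index (frame-0 correlation)
  below 0.7.
- **`ctperf.lesion`** — threshold segmentation (Tmax > 6 s
  hypoperfusion, relative CBF < 30% core), volumetry, mismatch, and
  DEFUSE-3 decisions (core < 70 mL, mismatch > 15 mL, ratio > 1.8) with
  margin-zone-filtered confusion matrices.
- **`ctperf.stats`** — ICC(2,1), median/SD of paired differences,
  Bland–Altman pairs, per-stratum cohort agreement tables.
- **`ctperf.dose`** — frame-proportion dose scaling of the two shipped
  Siemens reference protocols (CTDIvol 210 mGy / 27 frames and
  259 mGy / 30 frames) with NCCT/CTA comparison rows.
- **`ctperf.pipeline`** — the full experiment: simulate a cohort →
  decimate → process → QC → segment → decide → compare → dose table,
  deterministic under one seed.

The model core, in the field's standard notation: tissue enhancement is
`c_t(t) = CBF · (c_a ⊛ R)(t)` with residue function `R(t) = e^(−t/MTT)`;
deconvolution solves `min‖A k − c_t‖² + λ²‖k‖²` through the SVD of the
circulant AIF operator A with filter factors `σᵢ²/(σᵢ² + λ²)`,
`λ = 0.10 σ_max`; then `CBF = max_t k(t)`, `Tmax = argmax_t k(t)`,
`CBV = ∫c_t / ∫c_a`, `MTT = CBV/CBF`, and CBF/CBV are normalised to the
contralateral-hemisphere mean. See `docs/methods.md` for assumptions,
parameter rationale and known estimator biases.

## Worked example

Simulate one stroke case (17.1 mL true core inside a 57.6 mL
hypoperfused lesion), then process the same acquisition at every
sampling interval:

```python
from ctperf import *

spec = PhantomSpec(lesion=LesionSpec(center_mm=(20., 80., 40.),
                                     penumbra_radii_mm=(16., 34., 28.),
                                     core_radii_mm=(10., 22., 18.)))
case = build_phantom(spec, seed=42)
for f in (1, 2, 3, 4):
    sub = decimate(case.series, f)
    maps = compute_maps(sub, brain_mask=case.masks["brain"])
    hypo, core = segment(maps)
    rep = volumetry(hypo, core, maps.voxel_volume_ml)
    d = defuse3_decide(rep)
    print(f"dt={sub.dt:>3.1f} s ({sub.n_frames:>2} frames): "
          f"core {rep.core_volume:5.1f} mL, hypoperfusion "
          f"{rep.hypoperfusion_volume:5.1f} mL -> {d.eligible}")
```

prints

```
dt=1.5 s (27 frames): core  15.7 mL, hypoperfusion  59.3 mL -> treat
dt=3.0 s (14 frames): core  13.8 mL, hypoperfusion  58.6 mL -> treat
dt=4.5 s ( 9 frames): core  14.2 mL, hypoperfusion  59.0 mL -> treat
dt=6.0 s ( 7 frames): core   9.4 mL, hypoperfusion  58.3 mL -> treat
```

Halving the sampling (3.0 s) barely moves the volumes; at 6.0 s the core
estimate drifts (here −6 mL) while the treatment call is still unchanged
— the pattern the cohort-level statistics quantify. The same chain is
available from the shell (`ctperf simulate | sample | process | qc |
segment | decide | dose | cohort | report`); `ctperf report --n 50
--seed 0 --out run/` writes the full report bundle (volumes, agreement
tables, confusion matrices, QC summary, dose table, manifest) for a
50-case cohort.

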