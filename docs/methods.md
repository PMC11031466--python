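# Methods

This note documents the models, parameters and design choices behind
`ctperf`: what the synthetic cohort emulates, how the perfusion maps are
computed, what the tests establish and what they do not.

## The question

Dynamic brain CT perfusion (CTP) acquires a 4D series while an iodinated
bolus passes through the brain. The sampling interval (typically 1.5 s)
drives the radiation dose almost linearly: leaving out every second frame
halves it. The package quantifies what that decimation does to the derived
perfusion maps, to ischemic-lesion volumetry (Tmax > 6 s hypoperfusion,
relative CBF < 30% infarct core), and to perfusion-based thrombectomy
eligibility under the DEFUSE-3 criteria (core < 70 mL, mismatch > 15 mL,
mismatch ratio > 1.8).

Because clinical raw data are not redistributable, the study conditions
are reproduced by a fully synthetic phantom cohort with known ground
truth. Frame decimation keeps frames 0, f, 2f, ... of the same simulated
acquisition, so reference and subsampled analyses see identical anatomy,
noise and artifacts — exactly the paired design the question requires.

## Synthetic cohort

One case is a brain slab of 8 x 80 x 80 voxels at 5 x 2 x 2 mm (a ~1 L
two-hemisphere volume, left/right split along the x midline), scanned for
27 frames at 1.5 s. Per voxel the signal is

    HU(t) = baseline + anatomy texture + enhancement(t) + noise,

with a static smooth texture (SD 12 HU, in-plane correlation ~2 voxels)
standing in for gray/white/CSF contrast, and white Gaussian noise of
SD 2 HU per frame — representative of 80 kV perfusion series reconstructed
at 5 mm slice thickness.

Enhancement follows the indicator-dilution model: a gamma-variate arterial
bolus c_a(t) and tissue curves

    c_t(t) = CBF * (c_a(. - delay) * R)(t),   R(t) = exp(-t / MTT)

simulated on a dense 0.1 s grid and sampled at the frame times, so the
acquisition genuinely samples a continuous process. A small arterial blob
(peak ~140 HU) provides the AIF target. Lesions are concentric ellipsoids:
an infarct core (relative CBF 8–20% of normal, MTT 7–10 s) nested in a
hypoperfused penumbra (CBF 45–75%, MTT 5–7 s, arrival delay 6.2–13 s).
Core rCBF is kept well below the 30% operational threshold because that is
what the threshold was designed around — true core tissue flows far below it —
and because regularised deconvolution of heavily delayed, truncated curves
carries a known upward CBF bias. Severity tapers linearly to normal over
the outer 6% of the lesion radius (an oligemic rim): real penumbras shade
into normal tissue, and this gradient is precisely what makes lesion
boundaries sensitive to Tmax quantisation at coarse sampling.

Cohorts draw per-case circulation parameters — bolus arrival 6.5–9.5 s,
amplitude x0.6–1.4, gamma-variate width beta 1.2–2.2 (bolus FWHM roughly
5–9 s; narrow boluses are the classic coarse-sampling hazard) — and core
volume targets uniform on 0–110 mL so the 70 mL DEFUSE-3 threshold is
straddled; ~10% of cases have no lesion and ~12% hypoperfusion without
core. The default scenario mix is 90% clean and the remainder split over
the three artifact classes (late bolus, low contrast-to-noise, motion).
All randomness flows from one seed; identical seeds give bit-identical
series.

Artifact scenarios are constructed to sit on the intended side of the QC
thresholds: the late bolus arrives at 80% of the window (mean curve still
rising at the last frame), the weak bolus is scaled to a 5 HU mean-brain
peak (threshold 8 HU), and motion applies a 2-voxel (8 mm) circular
in-plane shift to frames 12–18, dropping the frame-0 correlation to ~0.5
(threshold 0.7, fatal below 0.3).

What the phantom does **not** emulate: beam hardening, scatter or any
projection-domain physics; spiral-mode nonuniform slice timing; partial
volume around vessels; realistic anatomy beyond a smooth texture; and
inter-subject anatomical variability. Passing tests therefore demonstrate
the behaviour of the processing chain under controlled hemodynamics, not
clinical-grade validation.

## Perfusion processing

Processing follows the standard deconvolution chain:

1. **Baseline subtraction.** Pre-contrast frames (estimated from the mean
   brain curve's 10%-rise point, minimum 2) are averaged and subtracted.
2. **Denoising.** Gaussian smoothing, in-plane FWHM 1.3 voxels (2.6 mm)
   and temporal sigma 2 s. The temporal filter is fixed in *physical*
   time: a finely sampled series admits more high-frequency noise and is
   smoothed over correspondingly more samples, so every sampling scheme
   sees a comparable noise floor. Without this, the max-over-time CBF
   estimator (below) is biased hardest at the *reference* sampling — 27
   noisy samples produce the largest maximum — which would invert the
   expected ranking of fine vs coarse sampling.
3. **AIF selection.** Candidate voxels are gated on peak height (60% of
   the mean of the eight tallest peaks — arterial curves tower over
   tissue), then scored by peak / (first moment x FWHM); the top 20
   curves are averaged. A manual voxel-mask mode bypasses scoring.
4. **Deconvolution.** The discrete convolution operator A is built from
   the AIF as a circulant matrix on a zero-padded grid (2x the window).
   The circulant (delay-preserving) embedding keeps residue peaks of
   late-arriving tissue inside the solution window, which is what makes
   Tmax a delay measure. Tikhonov regularisation via SVD filter factors
   s_i^2/(s_i^2 + lambda^2), lambda = lambda_rel * s_max.
5. **Maps.** CBF = max_t k(t); Tmax = argmax_t k(t) on the acquisition
   grid (no sub-grid interpolation — deliberately, so the quantisation
   that coarse sampling induces is visible); CBV = area(tissue)/area(AIF)
   by trapezoid; MTT = CBV/CBF (undefined at zero flow; such voxels are
   masked). CBF and CBV are normalised to the mean of the full
   contralateral hemisphere (the side with lower mean Tmax) and reported
   in percent.
6. **Motion correction.** Frames are realigned to frame 0 by exhaustive
   integer in-plane shifts (range ±6 voxels) maximising the masked
   correlation of z-mean projections; it is run when the minimum motion
   index falls below 0.9.

### Regularisation strength

`lambda_rel` defaults to **0.10**. Lower values leave noisy voxels with
spurious residue peaks (noisy Tmax); higher values smear the residue
onset, shifting delayed Tmax by more than one sample (at 0.15 a
delay-8 s voxel reads 10.5 s at dt = 1.5). 0.10 is the largest value at
which noiseless recovery stays within one sample for delay and ~5% for
relative CBF.

The discrete deconvolution carries a known systematic +~1-sample shift of
Tmax (rectangle-rule quadrature plus onset smoothing). It cancels in the
left/right comparison (normal tissue shifts identically) and is
documented rather than corrected, because the Tmax > 6 s threshold is
applied to relative-delay fields whose normal-tissue level is ~1 sample.

### Known estimator biases

Two biases matter for interpretation and are visible in the tests'
tolerances. First, max-over-time CBF has a positive noise bias that grows
with the number of samples — controlled, not removed, by the physical-time
denoising. Second, heavily delayed, dispersed curves truncated by the 42 s
window recover a relative CBF a few points high (e.g. true 20% reads
~24% at 1.5 s, worse at coarser sampling); this is an intrinsic cost of
short acquisition windows.

## Quality control

Three rules on the baseline-subtracted mean brain curve and the raw
frames: bolus peak later than 90% of the acquisition window (truncation),
peak below 8 HU (low CNR), minimum frame-0 Pearson correlation below 0.7
(motion). No flags = high quality, otherwise impaired. A stricter
"uninterpretable" state (flat bolus, zero-variance frame, or motion index
below 0.3) stands in for the visual review that removes fatally corrupted
scans; such cases are excluded from all agreement and decision analyses
at the reference sampling and logged.

A decimated series is judged against its own (shorter) window. Note that
decimation can *create* a truncation flag for boluses peaking close to
the 90% cut: with the peak between retained samples, the discrete peak
can land on the last frame. That is faithful behaviour — acquisition
problems get worse, never better, with fewer time points.

## Statistics

Agreement between reference (1.5 s) and subsampled volumes uses ICC(2,1)
— two-way random effects, absolute agreement, single measure, computed
from the classical mean-squares decomposition — plus the median and SD of
paired differences and Bland–Altman pairs. Absolute agreement is the
method-comparison choice: a systematic offset between samplings should
and does depress it. Mismatch-ratio agreement is restricted to cases with
core > 3 mL at *both* samplings (tiny denominators make ratios singular).

Treatment-decision agreement is a 2x2 confusion matrix of DEFUSE-3 calls
against the reference, after excluding cases whose reference values fall
in the margin zones (core 65–75 mL, mismatch 10–20 mL, ratio 1.6–2.0):
near a threshold, a 72 vs 69 mL difference is measurement noise, not a
decision reversal. For a case with zero core the mismatch ratio is
undefined; the ratio criterion is taken as satisfied when hypoperfusion
is present (the core→0 limit). The optional per-sampling widening of the
margin zones is off by default; the appropriate widening schedule is
ambiguous and the symmetric margin already absorbs the intended
uncertainty.

The sampling-robustness experiment reports difference statistics pooled
over six replicate 50-case clean cohorts (300 paired differences per
factor). A single cohort estimates each SD with ~10% standard error,
which is the same order as the difference between adjacent factors; the
pooled estimate makes the monotone growth of variability (and of decision
discordance) a stable, testable property instead of a seed lottery.
Problem sizes throughout — 50-case cohorts, 20-case noiseless recovery,
six replicates — were chosen as the smallest at which these statistics
stabilise.

## Radiation dose

Dose scales with the retained frame proportion ceil(n/f)/n. The shipped
reference protocols are the two 80 kV/180 mAs Siemens brain-perfusion
protocols (27 frames/100 mm, CTDIvol 210 mGy, DLP 2103 mGy·cm, 4.61 mSv;
30 frames/90 mm, 259 mGy, 2331 mGy·cm, 5.11 mSv) plus static NCCT and
CTA rows for comparison. Scaled CTDIvol/DLP round to integers (banker's
rounding by default; the 30-frame protocol at factor 2 lands exactly on
129.5 mGy, so that one cell is rounding-convention sensitive and the mode
is configurable). Published effective-dose figures for such protocols do
not follow pure frame-proportion scaling (vendor dose platforms model
over-ranging and scan-range end effects); the module reports the pure
scaling law and treats CTDIvol and frame counts as the reproducible
quantities. At factor 4 the retained proportion is 7/27, a ~74% dose
reduction, bringing perfusion CTP down to the order of a non-contrast
head CT.

## Numerical and degenerate-input choices

- Decimation phase is fixed at frame 0; `SamplingScheme` exposes the
  retained index set explicitly.
- The circulant operator is exactly invertible at lambda = 0 for
  operator-generated data (condition number ~60 for the default bolus);
  `solve` accepts full padded-length curves for that purpose.
- All-zero AIF, empty masks, non-uniform factors, out-of-grid lesions and
  unnested core masks raise ValueError.
- Zero-variance frames give NaN motion indices, a motion flag, and the
  uninterpretable state.
- Volumes are carried at full precision; no rounding before threshold
  comparisons.
- Hemisphere ties (identical mean Tmax) resolve by dictionary order of
  the hemisphere labels; in practice noise breaks ties.

## Limitations

- The phantom's lesion geometry (concentric ellipsoids with a thin ramp)
  is far simpler than real infarcts; Dice scores near 1 reflect that
  simplicity, and the acceptance threshold (0.9) should not be read as a
  clinical segmentation claim.
- Absolute agreement between this implementation and any commercial
  perfusion package cannot be claimed: deconvolution discretisation,
  regularisation policy and denoising differ between vendors and are
  unpublished. Self-consistency across samplings is the tested property.
- Effective-dose and DLP values beyond frame-proportion scaling are out
  of scope (no Monte-Carlo dosimetry).
- The spiral-mode nonuniform peripheral sampling of real scanners is not
  modelled; the phantom samples every slice simultaneously.
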