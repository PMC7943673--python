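# Methods

This note documents the models, conventions and numerical choices behind
`sirtdose`, and what the synthetic data can and cannot tell you about real
patients.

## Dosimetric model

The chain is counts → activity → dose:

1. **Relative calibration.** The administered activity is spread over a
   calibration region proportionally to the scintigraphic counts, zero
   outside it. Clinically the region is the liver plus the lungs (to account
   for hepato-pulmonary shunting); in the phantom the default lung shunt is
   0, so the region is the liver. Counts falling outside the calibration
   region (e.g. PSF spill-out beyond the dilated liver) are discarded by
   construction, which slightly concentrates activity inside — the same
   behaviour a count-proportional calibration has on real data.
2. **Local deposition.** Each voxel's dose is the total energy released by
   the complete decay of its assigned activity divided by its mass. The two
   underlying assumptions — permanent implant, local absorption of the β
   energy — make the dose map a rescaled activity map. No dose-kernel
   convolution, Monte-Carlo transport, bremsstrahlung or biologically
   effective dose.

Physical constants are configurable with defaults: ⁹⁰Y half-life 64.05 h,
mean β energy per decay 0.9267 MeV (⇒ ≈ 49.4 J released per GBq), tissue
density 1.05 g/mL applied uniformly. A uniform density (no CT-derived voxel
masses) is consistent with treating the liver as a homogeneous soft-tissue
medium at the 4–6 mm voxel scale used here.

Energy conservation is an invariant, not a tolerance target: summing
dose × voxel mass over the calibration region returns the administered
energy to floating-point precision, and `energy_audit` verifies this on
every run.

## Contours

* **Threshold targets**: voxels strictly above 10 % of the maximum count
  *within a VOI surrounding the liver* (the VOI-local maximum, so an
  extrahepatic hot spot cannot shift the threshold; a flag selects ≥ if
  inclusive ties are wanted). The mask is invariant under positive count
  rescaling and shrinks monotonically as the fraction grows.
* **Anatomy-derived contours**: liver and tumor masks on the emission grid;
  normal liver is the exact set difference. Tumor voxels outside the liver
  are clipped with a warning by default (configurable to an error).
* **Registration QA**: Dice overlap between the transferred anatomical liver
  and the emission-space liver, pass iff Dice ≥ 0.85 (inclusive — the
  boundary case passes). Failing patients are excluded from statistics but
  kept, flagged, in all tables.
* **Inter-operator reproducibility**: per contour pair, the coefficient of
  variation uses the n−1 standard deviation (for two values
  |vA−vB|/(√2·mean)); the summary is the RMS of per-pair CVs × 100.

## DVH metrics

The exact sort-based cumulative curve is the reference everywhere; the
fixed-width binned curve (default 0.1 Gy) exists only for export and
plotting. `D_x` is read from the exact curve as the largest listed dose whose
covered fraction still reaches x % — i.e. the step-function inverse, with the
smallest qualifying dose at ties. On a uniform dose this returns that dose
exactly, and for two equal voxels at 10/30 Gy it returns 10 Gy for D70
(covering 70 % of the volume requires the cooler half). Linear interpolation
across the step would instead report a dose received by *less* than x % of
the volume, so it is deliberately not used. Mean dose equals the integral of
the exact curve to 1e-9 relative, which serves as a cross-check in the tests.

TNR is computed from raw counts and contour volumes; since both contours
share one grid, the voxel volume cancels analytically and the ratio of mean
per-voxel counts is used, which keeps the uniform-counts case at unity to a
few ulp. TNR is intended for anatomy-based (disjoint tumor/normal-liver)
contours; overlap is an error.

## Synthetic phantom

The phantom is deliberately geometric: an axis-aligned ellipsoidal liver
(default aspect 1.3 : 1 : 0.8) holding spherical tumors, with
piecewise-uniform activity concentration (viable tumor : normal liver =
prescribed TNR; optional concentric necrotic core at zero activity). The
default grid mimics a SPECT matrix: 4.42 mm cubic voxels. Activity weights
are normalized so the liver total equals the administered activity exactly.
The true dose map is the local-deposition dose of the noiseless activity, so
downstream recovery tests have exact ground truth.

Imaging degradation is an isotropic Gaussian PSF (default FWHM 15 mm for the
SPECT-like channel, 8 mm for the PET-like channel) followed by per-voxel
Poisson noise scaled to a prescribed total count (default 5×10⁶). Scatter,
attenuation, partial-volume recovery and tomographic reconstruction are not
modelled — the pipeline's inputs are assumed already corrected, as they are
when a clinical workstation exports reconstructed volumes.

What this emulation does *not* show: real tumor geometry is irregular and
multifocal, activity within tumors is heterogeneous (so real D70 < Dm,
whereas the uniform phantom has D70 = Dm on noiseless data), and real
injections perfuse a selected arterial territory rather than the whole
liver. That last point matters for the threshold targets: with whole-liver
perfusion at clinically typical TNR, normal liver sits near 10 % of the
blurred tumor maximum, so the 10 % target can engulf most of the liver. The
tests therefore assert only the direction (target volume exceeds true tumor
volume), which is the behaviour that carries over to real data.

## Synthetic cohort

Patient covariates are lognormal with medians chosen to be representative of
a resin/glass radioembolization population: liver 1813 mL (σ_log 0.25),
tumor 203 mL (σ_log 1.0, capped at 35 % burden so a spherical tumor always
fits the liver), TNR medians 7.7 (resin) / 5.0 (glass) (σ_log 0.6), injected
activity 1.3 / 2.3 GBq (σ_log 0.45), resin fraction 25/48. Pre-treatment
dose metrics come from the closed-form two-compartment model (the tumor
absorbs the fraction TNR·V_t / (TNR·V_t + V_NL) of the activity);
post-treatment metrics add independent multiplicative lognormal jitter
(σ_log 0.2) representing microsphere-vs-surrogate distribution differences.

Outcomes follow an explicit generative model so the statistics layer has
recoverable truth:

* 6-month tumor control is Bernoulli with logit = logit(0.4) + ln(OR)·
  1{supramedian pre-treatment TNR within sphere type}, default OR 6; 15 % of
  patients lack follow-up and are excluded listwise from this analysis only.
* Overall survival is exponential with hazard ln 2 / 14 months for
  inframedian post-treatment tumor Dm and that hazard divided by the hazard
  ratio (default 2) for supramedian Dm, under independent uniform
  administrative censoring on [6, 48] months.

All coefficients live in `CohortParams`; nothing is hard-coded. Randomness
flows from a single seed through `numpy.random.SeedSequence` spawning
(stream 0: covariates; stream 1: outcomes; per-patient image seeds spawned
from the cohort seed and patient index), so cohorts and runs are
reproducible bit-for-bit.

Because the analysis dichotomizes *measured* metrics while outcomes were
generated from the *generative* metrics, label disagreement near the median
attenuates recovered effect sizes toward the null — the same regression
dilution that affects real dosimetric predictors. Recovery tests therefore
either use the noiseless path (exact recovery required) or calibrate
coverage over replicates.

## Statistical conventions

* Dichotomization is stratified by sphere type (resin and glass receive
  different activity scales); supramedian means strictly above the stratum
  median, so exact-median values are inframedian, and at most half a stratum
  is supramedian. Labels depend only on the value sets, never on patient
  order. The analysis-path `dichotomize` requires ≥ 2 patients per present
  stratum; the cohort generator's internal labelling tolerates a singleton
  stratum (its lone patient is inframedian by the strict rule).
* Logistic regression is a maximum-likelihood fit (statsmodels); for a
  binary covariate the ML odds ratio equals the 2×2 cross-product ratio
  ad/bc, which the tests verify exhaustively. A zero cell is reported as
  separation with an unbounded CI rather than a misleading Wald interval.
* Kaplan–Meier median: smallest time with survival ≤ 0.5 (lifelines
  convention) — uncensored {2, 4, 6, 8} has median 4. Cox uses Breslow tie
  handling; Wald 95 % CIs and two-sided p throughout.
* Bland–Altman reports the mean difference with its t-based 95 % CI and the
  1.96·SD limits of agreement.
* The multivariate gate keeps covariates with univariate p strictly below
  0.05 and drops the configured non-representative member of declared
  redundant pairs; an empty gate skips the multivariate step with a notice.

## Problem sizes

Default problem sizes were chosen to keep a full run interactive on a single
CPU: phantoms on 56×56×44 (pipeline) or 32×32×28 (unit tests) grids, 5×10⁶
counts per acquisition, cohorts of 20–48 patients for end-to-end runs, 100
replicates for calibration checks, n = 200–500 for effect-size recovery. A
20-patient end-to-end run takes a few seconds and the whole test suite,
including the exhaustive logistic sweep, well under a minute.

## Known limitations

* Ellipsoid/sphere geometry only; no multifocality, no respiratory motion,
  no deformable registration (only its Dice QA is modelled, via optional
  integer-voxel misalignment).
* Whole-liver perfusion makes threshold-target volumes systematically larger
  than in selective injections (direction preserved, magnitude not).
* Uniform tissue density; no lung compartment is rasterized (the lung shunt
  parameter only removes activity from the liver).
* Nearest-neighbor mask resampling between grids of different orientation is
  unsupported; reorient upstream.
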