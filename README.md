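# sirtdose

Voxel dosimetry and outcome analysis for ⁹⁰Y radioembolization (SIRT) of
liver tumors — from scintigraphic count volumes and contours to absorbed-dose
maps, dose–volume-histogram metrics and survival statistics, with a synthetic
phantom/cohort generator so the whole chain is testable without patient data.

## The problem

In selective internal radiation therapy, ⁹⁰Y-loaded microspheres are injected
into the hepatic artery and lodge preferentially in the hypervascularized
tumor. The absorbed dose actually delivered is estimated from emission
imaging: a ⁹⁹ᵐTc-MAA SPECT/CT acquired at treatment planning, and a
⁹⁰Y-microsphere PET/CT acquired after injection. Turning those count volumes
into clinically meaningful numbers requires a chain of steps — contouring,
relative activity calibration, voxel dosimetry, DVH metric extraction — and
the resulting metrics are then tested as predictors of tumor control and
overall survival. `sirtdose` implements that chain for researchers studying
dose–effect relationships in SIRT.

## Core model

**Relative calibration.** Total administered activity *A* is distributed over
a calibration region *R* (liver plus lungs) proportionally to counts:
*Aᵢ = A · cᵢ / Σ_{j∈R} cⱼ*. Only count ratios matter, so scanner
quantification scale cancels.

**Local deposition method (LDM).** The microsphere implant is permanent and
the β energy is absorbed in the emitting voxel, so the voxel dose is

  *Dᵢ = Aᵢ · E_GBq / mᵢ*  (Gy),

where *E_GBq = 10⁹ · (T½ / ln 2) · Ē_β ≈ 49.4 J per GBq* (T½ = 64.05 h,
Ē_β = 0.9267 MeV) and *mᵢ* is the voxel mass at uniform soft-tissue density.

**Metrics.** From the cumulative DVH of each contour: the mean dose *Dm* and
*D70*, the minimal dose covering the best-irradiated 70 % of the volume. From
the raw counts: the tumor-to-normal-liver uptake ratio

  *TNR = (CNTS_tum / V_tum) / (CNTS_NL / V_NL)*.

**Contours.** Two families: anatomy-derived masks (tumor drawn on
morphological imaging, transferred to the emission grid; QA'd by a Dice ≥ 0.85
rule against the emission-space liver) and 10 %-of-maximum threshold targets
segmented inside a VOI surrounding the liver.

**Statistics.** Pre/post agreement (Spearman, Wilcoxon signed-rank,
Bland–Altman), per-microsphere-type median dichotomization, univariate
logistic regression for 6-month tumor control, Kaplan–Meier/log-rank/Cox for
overall survival, and a p < 0.05 univariate gate before any multivariate fit.

## Worked example

```python
from scipy import ndimage
from sirtdose import (PhantomSpec, PhysicsConstants, make_phantom,
                      simulate_counts, threshold_contour, relative_calibration,
                      ldm_dose, cumulative_dvh, d_percent, mean_dose, tnr,
                      energy_audit, ContourMask)

spec = PhantomSpec(tnr_true=10.0, injected_activity_gbq=1.6, seed=42)
truth = make_phantom(spec)
counts = simulate_counts(truth)          # 15 mm PSF, 5e6 counts, Poisson noise
tumor, nl, liver = (truth.mask(r) for r in ("tumor", "normal_liver", "liver"))

constants = PhysicsConstants()
activity = relative_calibration(counts, liver, spec.injected_activity_gbq)
dose = ldm_dose(activity, constants)

print(f"measured TNR : {tnr(counts, tumor, nl):.2f}  (true {truth.tnr_true:.0f})")
print(f"tumor Dm     : {mean_dose(dose, tumor):.1f} Gy")
print(f"tumor D70    : {d_percent(cumulative_dvh(dose, tumor), 70):.1f} Gy")
voi = ContourMask(liver.grid,
                  ndimage.binary_dilation(liver.values, iterations=2).astype("uint8"))
target = threshold_contour(counts, voi, fraction=0.10)
print(f"10% target   : {target.volume_ml:.0f} mL (true tumor {tumor.volume_ml:.0f} mL)")
print(f"energy audit : {energy_audit(dose, constants, 1.6):.2e}")
```

prints

```
measured TNR : 7.26  (true 10)
tumor Dm     : 177.9 Gy
tumor D70    : 154.6 Gy
10% target   : 628 mL (true tumor 204 mL)
energy audit : 1.80e-16
```

The measured TNR sits below the prescribed 10 because the 15 mm point-spread
function spills tumor counts into the surrounding liver; for the same reason
the 10 % threshold target is much larger than the true tumor. The energy
audit confirms that calibration followed by local deposition conserves the
administered energy to machine precision.

A full synthetic cohort (phantoms, both contour families, dose maps, metric
tables, QA report, agreement/predictor statistics, manifest) runs from the
command line:

```bash
sirtdose run --n-patients 20 --seed 17 --out runs/demo
```

Other subcommands (`phantom`, `contour`, `dose`, `dvh`, `stats`) wrap the
individual stages; see `sirtdose --help`.

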