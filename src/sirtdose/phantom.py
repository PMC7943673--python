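"""Synthetic phantoms and cohorts for hepatic radioembolization dosimetry.

Real inputs to this pipeline are scintigraphic count volumes (a
planning-surrogate SPECT before treatment, a microsphere PET after) plus
liver and tumor contours and clinical outcomes — none of which can ship
with the package.  This module fabricates all of them with known ground
truth:

* :func:`make_phantom` builds an ellipsoidal liver holding one or more
  spherical tumors, fills it with a piecewise-uniform activity
  concentration at a prescribed tumor-to-normal ratio (TNR), and derives
  the exact activity and dose maps.
* :func:`simulate_counts` degrades the true activity into a
  scintigraphy-like count volume: isotropic Gaussian point-spread blur
  followed by per-voxel Poisson noise, scaled to a prescribed total
  count.  Scatter and attenuation are assumed corrected upstream.
* :func:`make_cohort` draws a patient cohort whose 6-month tumor-control
  and overall-survival outcomes depend on the dose metrics through an
  explicit generative model (logistic in supramedian TNR; exponential
  survival with a proportional hazard on supramedian mean tumor dose),
  so the downstream statistics have recoverable ground truth.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning: stream 0 drives geometry/dose sampling, stream 1 the outcome
draws, and per-patient image seeds are spawned from the patient index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .dosimetry import PhysicsConstants, ldm_dose
from .errors import CohortError, GeometryError, ParameterError
from .stats import PatientRecord
from .volumes import ActivityMap, ContourMask, CountVolume, DoseMap, VoxelGrid

#: Gaussian FWHM of the point-spread function per emulated modality (mm).
SPECT_PSF_FWHM_MM = 15.0
PET_PSF_FWHM_MM = 8.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TumorSphere:
    """A spherical tumor: center (mm, physical coordinates) and radius (mm)."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("tumor radius must be positive")

    @classmethod
    def from_volume(cls, center_mm, volume_ml: float) -> "TumorSphere":
        r = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        return cls(tuple(float(c) for c in center_mm), r)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic liver phantom.

    The liver is an axis-aligned ellipsoid; tumors are spheres that must
    lie inside it.  ``necrotic_core_fraction`` is the fraction of each
    tumor's volume occupied by a concentric, activity-free core.
    ``tnr_true`` is the prescribed ratio of viable-tumor to normal-liver
    activity concentration.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (4.42, 4.42, 4.42)
    liver_center_mm: tuple[float, float, float] = (141.0, 141.0, 106.0)
    liver_semiaxes_mm: tuple[float, float, float] = (95.0, 75.0, 60.0)
    tumors: tuple[TumorSphere, ...] = (TumorSphere((120.0, 130.0, 110.0), 36.5),)
    necrotic_core_fraction: float = 0.0
    tnr_true: float = 7.0
    injected_activity_gbq: float = 1.6
    lung_shunt: float = 0.0
    psf_fwhm_mm: float = SPECT_PSF_FWHM_MM
    total_counts: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tnr_true <= 0:
            raise ParameterError("tnr_true must be positive")
        if self.injected_activity_gbq <= 0:
            raise ParameterError("injected activity must be positive")
        if not 0.0 <= self.necrotic_core_fraction < 1.0:
            raise ParameterError("necrotic core fraction must lie in [0, 1)")
        if not 0.0 <= self.lung_shunt < 1.0:
            raise ParameterError("lung shunt must lie in [0, 1)")
        if self.psf_fwhm_mm < 0:
            raise ParameterError("PSF FWHM must be nonnegative")
        if self.total_counts <= 0:
            raise ParameterError("total counts must be positive")
        c = np.array(self.liver_center_mm)
        a = np.array(self.liver_semiaxes_mm)
        if np.any(a <= 0):
            raise GeometryError("liver semi-axes must be positive")
        for t in self.tumors:
            shrunk = a - t.radius_mm
            if np.any(shrunk <= 0) or np.sum(((np.array(t.center_mm) - c) / shrunk) ** 2) > 1.0:
                raise GeometryError(
                    f"tumor at {t.center_mm} (r={t.radius_mm:.1f} mm) is not "
                    "contained in the liver ellipsoid"
                )

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.voxel_size_mm)


# label codes in PhantomTruth.labels
BACKGROUND, NORMAL_LIVER, VIABLE_TUMOR, NECROSIS = 0, 1, 2, 3


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: labels, activity, dose and metrics.

    ``labels``: 0 background, 1 normal liver, 2 viable tumor, 3 necrotic
    core.  ``activity`` holds GBq per voxel; ``dose`` the exact
    local-deposition dose (Gy).  ``tnr_true`` is the concentration ratio
    measured on the noiseless activity volume with the anatomical tumor
    contour (viable + necrosis) — it equals the prescribed ratio exactly
    when there is no necrosis.  ``region_metrics`` maps region name to
    ``{"dm_gy": ..., "d70_gy": ..., "volume_ml": ...}``.
    """

    spec: PhantomSpec
    labels: np.ndarray
    activity: ActivityMap
    dose: DoseMap
    tnr_true: float
    region_metrics: dict[str, dict[str, float]]

    @property
    def grid(self) -> VoxelGrid:
        return self.activity.grid

    def mask(self, region: str) -> ContourMask:
        """Binary mask for 'liver', 'tumor', 'normal_liver' or 'necrosis'."""
        sel = {
            "liver": self.labels > 0,
            "tumor": (self.labels == VIABLE_TUMOR) | (self.labels == NECROSIS),
            "normal_liver": self.labels == NORMAL_LIVER,
            "necrosis": self.labels == NECROSIS,
        }[region]
        return ContourMask(self.grid, sel.astype(np.uint8), label=region)

    def concentration_gbq_per_ml(self) -> np.ndarray:
        return self.activity.values / self.grid.voxel_volume_ml


def make_phantom(
    spec: PhantomSpec,
    constants: PhysicsConstants | None = None,
) -> PhantomTruth:
    """Rasterize a phantom spec into label, activity and true dose volumes.

    Activity concentration is uniform within normal liver and within
    viable tumor, with the viable:normal ratio equal to ``tnr_true``;
    necrotic cores carry no activity.  The liver-summed activity equals
    ``injected_activity_gbq * (1 - lung_shunt)``.  The true dose map is
    the local-deposition dose of the noiseless activity.
    """
    constants = constants or PhysicsConstants()
    grid = spec.grid
    axes = [
        np.arange(n, dtype=float) * s
        for n, s in zip(grid.shape, grid.voxel_size_mm)
    ]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij", sparse=True)
    c = spec.liver_center_mm
    a = spec.liver_semiaxes_mm
    liver = (
        ((xs - c[0]) / a[0]) ** 2
        + ((ys - c[1]) / a[1]) ** 2
        + ((zs - c[2]) / a[2]) ** 2
    ) <= 1.0
    if not liver.any():
        raise GeometryError("liver ellipsoid contains no voxels on this grid")
    labels = np.where(liver, NORMAL_LIVER, BACKGROUND).astype(np.uint8)
    for t in spec.tumors:
        d2 = (
            (xs - t.center_mm[0]) ** 2
            + (ys - t.center_mm[1]) ** 2
            + (zs - t.center_mm[2]) ** 2
        )
        inside = d2 <= t.radius_mm**2
        if not inside.any():
            raise GeometryError(
                f"tumor at {t.center_mm} is below voxel resolution (r={t.radius_mm} mm)"
            )
        labels[inside] = VIABLE_TUMOR
        if spec.necrotic_core_fraction > 0:
            core_r = t.radius_mm * spec.necrotic_core_fraction ** (1.0 / 3.0)
            labels[d2 <= core_r**2] = NECROSIS

    # piecewise-uniform concentration with prescribed viable:normal ratio;
    # weights are normalized so the liver total is exact in float
    rel = np.zeros(grid.shape)
    rel[labels == NORMAL_LIVER] = 1.0
    rel[labels == VIABLE_TUMOR] = spec.tnr_true
    total_rel = rel.sum()
    if total_rel <= 0:
        raise GeometryError("phantom carries no activity (all liver is necrotic?)")
    liver_gbq = spec.injected_activity_gbq * (1.0 - spec.lung_shunt)
    activity = ActivityMap(grid, rel * (liver_gbq / total_rel))
    dose = ldm_dose(activity, constants)

    tumor_sel = (labels == VIABLE_TUMOR) | (labels == NECROSIS)
    nl_sel = labels == NORMAL_LIVER
    conc_t = activity.values[tumor_sel].sum() / tumor_sel.sum()
    conc_n = activity.values[nl_sel].sum() / nl_sel.sum()
    tnr_true = float(conc_t / conc_n)

    from .dvh import cumulative_dvh, d_percent, mean_dose  # local import, no cycle

    region_metrics = {}
    for region in ("liver", "tumor", "normal_liver"):
        sel = {
            "liver": labels > 0,
            "tumor": tumor_sel,
            "normal_liver": nl_sel,
        }[region]
        mask = ContourMask(grid, sel.astype(np.uint8), label=region)
        curve = cumulative_dvh(dose, mask)
        region_metrics[region] = {
            "dm_gy": mean_dose(dose, mask),
            "d70_gy": d_percent(curve, 70.0),
            "volume_ml": mask.volume_ml,
        }
    return PhantomTruth(
        spec=spec,
        labels=labels,
        activity=activity,
        dose=dose,
        tnr_true=tnr_true,
        region_metrics=region_metrics,
    )


def simulate_counts(
    truth: PhantomTruth,
    psf_fwhm_mm: float | None = None,
    total_counts: int | None = None,
    seed: int | None = None,
    modality: str = "SPECT-like",
    poisson_noise: bool = True,
) -> CountVolume:
    """Emulate a scintigraphic acquisition of the phantom's activity.

    The expected count map is the true activity blurred by an isotropic
    Gaussian PSF and rescaled so its total equals ``total_counts``; the
    observed counts are independent Poisson draws per voxel, so the
    result is deterministic given ``seed``.  With zero blur and large
    counts the activity shape is recovered up to one global scale
    factor; ``poisson_noise=False`` returns the expected (noise-free)
    count map itself.
    """
    spec = truth.spec
    fwhm = spec.psf_fwhm_mm if psf_fwhm_mm is None else psf_fwhm_mm
    n_total = spec.total_counts if total_counts is None else total_counts
    seed = spec.seed if seed is None else seed
    if fwhm < 0:
        raise ParameterError("PSF FWHM must be nonnegative")
    if n_total <= 0:
        raise ParameterError("total counts must be positive")
    lam = truth.activity.values.astype(float)
    if fwhm > 0:
        sigma_vox = [
            fwhm * _FWHM_TO_SIGMA / s for s in truth.grid.voxel_size_mm
        ]
        lam = ndimage.gaussian_filter(lam, sigma=sigma_vox, mode="constant")
    lam = lam * (float(n_total) / lam.sum())
    if not poisson_noise:
        return CountVolume(truth.grid, lam, modality=modality)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(float)
    return CountVolume(truth.grid, counts, modality=modality)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a synthetic treatment cohort.

    Patient-level covariates are lognormal with medians loosely matched
    to a resin/glass radioembolization population (liver ~1.8 L, tumor
    ~200 mL, TNR medians 7.7 resin / 5.0 glass, injected activity 1.3 /
    2.3 GBq).  Outcomes follow an explicit model: the 6-month
    tumor-control probability is logistic with odds ratio
    ``control_or_true`` for supramedian pre-treatment TNR, and survival
    is exponential with hazard ratio ``os_hr_true`` for *inframedian*
    mean tumor dose (supramedian dose protects), with independent
    uniform administrative censoring.
    """

    resin_fraction: float = 25.0 / 48.0
    liver_ml_median: float = 1813.0
    liver_ml_sigma_log: float = 0.25
    tumor_ml_median: float = 203.0
    tumor_ml_sigma_log: float = 1.0
    tnr_median: dict = field(default_factory=lambda: {"resin": 7.7, "glass": 5.0})
    tnr_sigma_log: float = 0.6
    activity_gbq_median: dict = field(default_factory=lambda: {"resin": 1.3, "glass": 2.3})
    activity_sigma_log: float = 0.45
    post_jitter_sigma_log: float = 0.2
    control_metric: str = "TNR-Pre-C_MRI"
    control_or_true: float = 6.0
    control_baseline_p: float = 0.4
    missing_followup_p: float = 0.15
    survival_metric: str = "Dm-Post-C_MRI"
    os_hr_true: float = 2.0
    os_median_inframedian_months: float = 14.0
    censor_window_months: tuple[float, float] = (6.0, 48.0)


@dataclass
class Cohort:
    """A generated cohort: patient records plus the generative manifest.

    ``manifest`` records every parameter, the master seed and per-patient
    generative truth (covariates, supramedian flags, event probabilities)
    so recovery tests can compare estimates with the truth.
    """

    records: list[PatientRecord]
    params: CohortParams
    seed: int
    manifest: dict

    def __len__(self) -> int:
        return len(self.records)


def _closed_form_metrics(
    liver_ml: float,
    tumor_ml: float,
    tnr: float,
    activity_gbq: float,
    constants: PhysicsConstants,
) -> dict[str, float]:
    """Dose metrics of the uniform two-compartment model, in closed form.

    With uniform concentrations the tumor absorbs the fraction
    ``tnr*V_t / (tnr*V_t + V_nl)`` of the administered activity; the dose
    is uniform per compartment so Dm and D70 coincide.
    """
    v_nl = liver_ml - tumor_ml
    if v_nl <= 0:
        raise ParameterError("tumor volume must be smaller than liver volume")
    a_t = activity_gbq * tnr * tumor_ml / (tnr * tumor_ml + v_nl)
    mass_t_kg = tumor_ml * constants.tissue_density_g_per_ml / 1000.0
    dm_t = a_t * constants.energy_per_gbq_j / mass_t_kg
    return {"dm_tumor_gy": dm_t, "tumor_activity_gbq": a_t}


def make_cohort(
    n: int = 48,
    params: CohortParams | None = None,
    seed: int = 0,
    constants: PhysicsConstants | None = None,
) -> Cohort:
    """Draw a synthetic cohort with dose-dependent outcomes.

    Covariates (sphere type, liver/tumor volume, TNR, injected activity)
    are sampled per patient; pre-treatment dose metrics come from the
    closed-form uniform-compartment model and post-treatment metrics add
    independent multiplicative lognormal jitter.  Outcomes are then drawn
    from the logistic (tumor control) and exponential proportional-hazard
    (overall survival) models described in :class:`CohortParams`.
    """
    if n < 2:
        raise CohortError(f"a cohort needs at least 2 patients, got n={n}")
    params = params or CohortParams()
    constants = constants or PhysicsConstants()
    ss = np.random.SeedSequence(seed)
    rng_cov, rng_out = [np.random.default_rng(s) for s in ss.spawn(2)]

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(n):
        sphere = "resin" if rng_cov.random() < params.resin_fraction else "glass"
        liver_ml = params.liver_ml_median * np.exp(
            rng_cov.normal(0.0, params.liver_ml_sigma_log))
        tumor_ml = params.tumor_ml_median * np.exp(
            rng_cov.normal(0.0, params.tumor_ml_sigma_log))
        # cap burden at 35% so the spherical tumor always fits the liver
        tumor_ml = min(tumor_ml, 0.35 * liver_ml)
        tnr = params.tnr_median[sphere] * np.exp(
            rng_cov.normal(0.0, params.tnr_sigma_log))
        act = params.activity_gbq_median[sphere] * np.exp(
            rng_cov.normal(0.0, params.activity_sigma_log))
        pre = _closed_form_metrics(liver_ml, tumor_ml, tnr, act, constants)
        jit_tnr = np.exp(rng_cov.normal(0.0, params.post_jitter_sigma_log))
        jit_dm = np.exp(rng_cov.normal(0.0, params.post_jitter_sigma_log))
        metrics = {
            "liver_ml": liver_ml,
            "tumor_ml": tumor_ml,
            "TNR-Pre-C_MRI": tnr,
            "TNR-Post-C_MRI": tnr * jit_tnr,
            "Dm-Pre-C_MRI": pre["dm_tumor_gy"],
            "D70-Pre-C_MRI": pre["dm_tumor_gy"],
            "Dm-Post-C_MRI": pre["dm_tumor_gy"] * jit_dm,
            "D70-Post-C_MRI": pre["dm_tumor_gy"] * jit_dm,
        }
        records.append(PatientRecord(
            id=f"P{i:03d}", sphere_type=sphere, injected_gbq=float(act),
            metrics={k: float(v) for k, v in metrics.items()},
        ))
        truth_rows.append({
            "id": f"P{i:03d}", "sphere_type": sphere,
            "tnr_true": float(tnr), "dm_tumor_true_gy": float(pre["dm_tumor_gy"]),
        })

    # outcome draws conditioned on supramedian status of the named metrics;
    # unlike the analysis-path dichotomization this tolerates a singleton
    # sphere-type stratum (its lone patient sits at its median: inframedian)
    def _supra(metric: str) -> dict[str, bool]:
        by_type: dict[str, list[tuple[str, float]]] = {}
        for r in records:
            by_type.setdefault(r.sphere_type, []).append((r.id, r.metrics[metric]))
        labels = {}
        for vals in by_type.values():
            med = float(np.median([v for _, v in vals]))
            labels.update({pid: v > med for pid, v in vals})
        return labels

    control_supra = _supra(params.control_metric)
    surv_supra = _supra(params.survival_metric)
    control_medians = {
        t: float(np.median([r.metrics[params.control_metric]
                            for r in records if r.sphere_type == t]))
        for t in {r.sphere_type for r in records}
    }
    surv_medians = {
        t: float(np.median([r.metrics[params.survival_metric]
                            for r in records if r.sphere_type == t]))
        for t in {r.sphere_type for r in records}
    }
    logit0 = np.log(params.control_baseline_p / (1.0 - params.control_baseline_p))
    log_or = np.log(params.control_or_true)
    lam0 = np.log(2.0) / params.os_median_inframedian_months
    for rec, row in zip(records, truth_rows):
        supra_c = control_supra[rec.id]
        p_control = 1.0 / (1.0 + np.exp(-(logit0 + log_or * supra_c)))
        if rng_out.random() < params.missing_followup_p:
            rec.tumor_control_6mo = None
        else:
            rec.tumor_control_6mo = bool(rng_out.random() < p_control)
        supra_s = surv_supra[rec.id]
        hazard = lam0 / params.os_hr_true if supra_s else lam0
        t_event = rng_out.exponential(1.0 / hazard)
        t_censor = rng_out.uniform(*params.censor_window_months)
        rec.os_months = float(min(t_event, t_censor))
        rec.death_observed = bool(t_event <= t_censor)
        row.update({
            "supramedian_control_metric": supra_c,
            "p_control": p_control,
            "supramedian_survival_metric": supra_s,
            "hazard_per_month": hazard,
        })

    manifest = {
        "n": n,
        "seed": seed,
        "params": {k: v for k, v in asdict(params).items()},
        "dichotomization_medians": {
            params.control_metric: control_medians,
            params.survival_metric: surv_medians,
        },
        "patients": truth_rows,
    }
    return Cohort(records=records, params=params, seed=seed, manifest=manifest)


def patient_phantom_spec(
    record: PatientRecord,
    index: int,
    seed: int,
    grid_shape: tuple[int, int, int] = (56, 56, 44),
    voxel_size_mm: float = 4.42,
    psf_fwhm_mm: float = SPECT_PSF_FWHM_MM,
    total_counts: int = 5_000_000,
) -> PhantomSpec:
    """Build an imaging phantom for one cohort patient.

    The liver ellipsoid and tumor sphere are scaled to the patient's
    sampled volumes (aspect ratio fixed at 1.3 : 1 : 0.8) and centered on
    the grid; the per-patient image seed is spawned from the cohort seed
    and the patient index so pre/post simulations are reproducible.
    """
    liver_ml = record.metrics["liver_ml"]
    tumor_ml = record.metrics["tumor_ml"]
    tnr = record.metrics["TNR-Pre-C_MRI"]
    aspect = np.array([1.3, 1.0, 0.8])
    scale = (liver_ml * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    center = tuple(
        float(n * voxel_size_mm / 2.0) for n in grid_shape
    )
    # keep the ellipsoid inside the grid with a one-voxel margin
    scale_max = min(
        (c - 2.0 * voxel_size_mm) / a for c, a in zip(center, aspect)
    )
    scale = min(scale, scale_max)
    semi = tuple(float(v) for v in aspect * scale)
    r_t = (3.0 * tumor_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_t = min(r_t, 0.95 * min(semi))   # containment cap for very large tumors
    # offset the tumor along the longest axis, staying inside the ellipsoid
    max_off = max(semi[0] - r_t, 0.0)
    offset = 0.4 * max_off
    t_center = (center[0] + offset, center[1], center[2])
    child = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    img_seed = int(child.generate_state(1)[0] % (2**31))
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=(voxel_size_mm,) * 3,
        liver_center_mm=center,
        liver_semiaxes_mm=semi,
        tumors=(TumorSphere(t_center, r_t),),
        tnr_true=float(tnr),
        injected_activity_gbq=float(record.injected_gbq),
        psf_fwhm_mm=psf_fwhm_mm,
        total_counts=total_counts,
        seed=img_seed,
    )
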