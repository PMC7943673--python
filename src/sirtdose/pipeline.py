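"""End-to-end cohort runs: phantom -> contours -> dose -> metrics -> stats.

A run is fully described by a :class:`RunConfig`; given the same config
and seed, two runs produce identical tables.  For every synthetic
patient the pipeline simulates pre-treatment (SPECT-like) and
post-treatment (PET-like) count volumes, derives both contour families
(anatomy-based masks and percentage-of-maximum threshold targets),
checks registration QA, computes the local-deposition dose map and the
DVH metrics, and finally runs the outcome statistics on the *measured*
metrics while the generative truth stays available in the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .contours import (
    ContourSet,
    dice,
    registration_qa,
    threshold_contour,
)
from .dosimetry import PhysicsConstants, energy_audit, ldm_dose, relative_calibration
from .dvh import contour_metrics
from .errors import SirtDoseError
from .phantom import (
    CohortParams,
    PET_PSF_FWHM_MM,
    SPECT_PSF_FWHM_MM,
    make_cohort,
    make_phantom,
    patient_phantom_spec,
    simulate_counts,
)
from .stats import (
    agreement_suite,
    dichotomize,
    logistic_univariate,
    multivariate_gate,
    records_to_frame,
    survival_suite,
)
from .volumes import ContourMask

logger = logging.getLogger(__name__)

#: metric names analysed for outcome prediction
PRE_METRICS = ("Dm-Pre-C_SPECT", "D70-Pre-C_SPECT", "Dm-Pre-C_MRI",
               "D70-Pre-C_MRI", "TNR-Pre-C_MRI")
POST_METRICS = ("Dm-Post-C_PET", "D70-Post-C_PET", "Dm-Post-C_MRI",
                "D70-Post-C_MRI", "TNR-Post-C_MRI")
PAIRED = (
    ("Dm-Pre-C_SPECT", "Dm-Post-C_PET"),
    ("D70-Pre-C_SPECT", "D70-Post-C_PET"),
    ("Dm-Pre-C_MRI", "Dm-Post-C_MRI"),
    ("D70-Pre-C_MRI", "D70-Post-C_MRI"),
    ("TNR-Pre-C_MRI", "TNR-Post-C_MRI"),
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a cohort run."""

    n_patients: int = 20
    seed: int = 0
    grid_shape: tuple[int, int, int] = (56, 56, 44)
    voxel_size_mm: float = 4.42
    threshold_fraction: float = 0.10
    dice_threshold: float = 0.85
    half_life_h: float = 64.05
    mean_energy_per_decay_mev: float = 0.9267
    tissue_density_g_per_ml: float = 1.05
    dvh_bin_width_gy: float = 0.1
    alpha: float = 0.05
    psf_pre_fwhm_mm: float = SPECT_PSF_FWHM_MM
    psf_post_fwhm_mm: float = PET_PSF_FWHM_MM
    total_counts_pre: int = 5_000_000
    total_counts_post: int = 5_000_000
    voi_dilation_voxels: int = 2
    misalign_shift_voxels: int = 0
    save_volumes: bool = False
    redundant_pairs: tuple[tuple[str, str], ...] = (
        ("TNR-Pre-C_MRI", "TNR-Post-C_MRI"),
    )
    cohort: dict = field(default_factory=dict)

    @property
    def constants(self) -> PhysicsConstants:
        return PhysicsConstants(
            half_life_h=self.half_life_h,
            mean_energy_per_decay_mev=self.mean_energy_per_decay_mev,
            tissue_density_g_per_ml=self.tissue_density_g_per_ml,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "redundant_pairs" in raw:
            raw["redundant_pairs"] = tuple(tuple(p) for p in raw["redundant_pairs"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _shift_mask(mask: ContourMask, shift: int) -> ContourMask:
    """Translate a mask by whole voxels along the first axis (QA testing)."""
    if shift == 0:
        return mask
    vals = np.roll(mask.values, shift, axis=0)
    if shift > 0:
        vals[:shift] = 0
    else:
        vals[shift:] = 0
    return ContourMask(mask.grid, vals, label=mask.label)


def measure_patient(
    record,
    index: int,
    config: RunConfig,
) -> dict:
    """Simulate and measure one patient; returns metrics + QA info.

    The anatomy-derived (radiologic) contours are the phantom's true
    masks, optionally shifted to emulate a failed registration; the
    threshold targets are segmented on each timepoint's own counts.
    """
    constants = config.constants
    spec = patient_phantom_spec(
        record, index, config.seed,
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        psf_fwhm_mm=config.psf_pre_fwhm_mm,
        total_counts=config.total_counts_pre,
    )
    truth = make_phantom(spec, constants)
    liver = truth.mask("liver")
    tumor_true = truth.mask("tumor")

    # emulated radiologic contours after registration onto the emission grid
    tumor_mri = _shift_mask(tumor_true, config.misalign_shift_voxels)
    liver_mri = _shift_mask(liver, config.misalign_shift_voxels)
    qa_dice = dice(liver_mri, liver)
    qa_pass = registration_qa(qa_dice, config.dice_threshold, patient_id=record.id)
    cset = ContourSet.from_liver_tumor(
        liver, tumor_mri & liver, provenance="C_MRI")

    voi_vals = ndimage.binary_dilation(
        liver.values, iterations=config.voi_dilation_voxels)
    voi = ContourMask(liver.grid, voi_vals.astype(np.uint8), label="voi")

    out = {
        "id": record.id,
        "qa_dice": qa_dice,
        "qa_pass": qa_pass,
        "tumor_true_ml": tumor_true.volume_ml,
        "liver_ml": liver.volume_ml,
    }
    metrics: dict[str, float] = {}
    for timepoint, psf, ncounts, thr_name, seed_off in (
        ("Pre", config.psf_pre_fwhm_mm, config.total_counts_pre, "C_SPECT", 0),
        ("Post", config.psf_post_fwhm_mm, config.total_counts_post, "C_PET", 1),
    ):
        counts = simulate_counts(
            truth, psf_fwhm_mm=psf, total_counts=ncounts,
            seed=spec.seed + seed_off,
            modality="SPECT-like" if thr_name == "C_SPECT" else "PET-like",
        )
        target = threshold_contour(counts, voi, fraction=config.threshold_fraction)
        activity = relative_calibration(counts, liver, record.injected_gbq)
        dosemap = ldm_dose(activity, constants)
        out[f"energy_audit_{timepoint.lower()}"] = energy_audit(
            dosemap, constants, record.injected_gbq)
        m_mri = contour_metrics(
            dosemap, cset.tumor, f"Dm-{timepoint}-C_MRI",
            counts=counts, normal_liver_mask=cset.normal)
        m_thr = contour_metrics(dosemap, target, f"Dm-{timepoint}-{thr_name}")
        metrics[f"Dm-{timepoint}-C_MRI"] = m_mri.dm_gy
        metrics[f"D70-{timepoint}-C_MRI"] = m_mri.d70_gy
        metrics[f"TNR-{timepoint}-C_MRI"] = m_mri.tnr
        metrics[f"Dm-{timepoint}-{thr_name}"] = m_thr.dm_gy
        metrics[f"D70-{timepoint}-{thr_name}"] = m_thr.d70_gy
        metrics[f"target_{thr_name}_ml"] = m_thr.volume_ml
    out["metrics"] = metrics
    out["tnr_true"] = truth.tnr_true
    return out


def run_pipeline(config: RunConfig, output_dir: str | Path) -> Path:
    """Execute a full synthetic-cohort analysis; returns the run directory.

    Emits per-patient metric and QA tables, agreement and predictor
    tables, Kaplan-Meier curve points and a JSON manifest (config,
    package version, seeds).  QA failures are excluded from statistics
    but kept, flagged, in the tables.
    """
    t0 = time.time()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(
        n=config.n_patients,
        params=CohortParams(**config.cohort) if config.cohort else None,
        seed=config.seed,
        constants=config.constants,
    )

    qa_rows, metric_rows = [], []
    for i, rec in enumerate(cohort.records):
        t_stage = time.time()
        try:
            res = measure_patient(rec, i, config)
        except SirtDoseError as exc:
            raise SirtDoseError(f"[measure:{rec.id}] {exc}") from exc
        # measured metrics replace the generative closed-form values
        rec.metrics.update(res["metrics"])
        rec.metrics["qa_pass"] = float(res["qa_pass"])
        qa_rows.append({
            "id": rec.id, "contour": "liver", "dice": res["qa_dice"],
            "qa_pass": res["qa_pass"],
            "energy_audit_pre": res["energy_audit_pre"],
            "energy_audit_post": res["energy_audit_post"],
        })
        logger.info("patient %s measured in %.2f s (QA %s)",
                    rec.id, time.time() - t_stage,
                    "pass" if res["qa_pass"] else "FAIL")

    frame = records_to_frame(cohort.records)
    frame.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(qa_rows).to_csv(out / "qa.csv", index=False)

    analyzed = [r for r in cohort.records if r.metrics.get("qa_pass", 1.0) >= 1.0]
    n_excluded = len(cohort.records) - len(analyzed)
    if n_excluded:
        logger.warning("%d patient(s) excluded from statistics by registration QA",
                       n_excluded)

    # pre vs post agreement per paired metric
    agree_rows = []
    aframe = records_to_frame(analyzed)
    for pre_name, post_name in PAIRED if len(analyzed) else ():
        try:
            res = agreement_suite(aframe[pre_name].values, aframe[post_name].values)
        except SirtDoseError:
            continue
        agree_rows.append({
            "pre_metric": pre_name, "post_metric": post_name, "n": res["n"],
            "spearman_rho": res["spearman_rho"], "spearman_p": res["spearman_p"],
            "wilcoxon_p": res["wilcoxon_p"],
            "ba_mean_diff": res["bland_altman"]["mean_diff"],
            "ba_ci_low": res["bland_altman"]["ci95"][0],
            "ba_ci_high": res["bland_altman"]["ci95"][1],
        })
    pd.DataFrame(agree_rows).to_csv(out / "agreement.csv", index=False)

    # predictor tables: tumor control (logistic) and OS (KM/Cox)
    pred_rows, km_rows = [], []
    control_ps, os_ps = {}, {}
    for name in (PRE_METRICS + POST_METRICS) if len(analyzed) else ():
        try:
            dich = dichotomize(analyzed, name)
        except SirtDoseError:
            continue
        supra = np.array([dich.supramedian(r.id) for r in analyzed])
        has_fu = np.array([r.tumor_control_6mo is not None for r in analyzed])
        row = {"metric": name}
        row.update({f"median_{k}": v for k, v in dich.medians.items()})
        if has_fu.sum() >= 4:
            ctrl = np.array([bool(r.tumor_control_6mo) for r in
                             np.array(analyzed, dtype=object)[has_fu]])
            try:
                lr = logistic_univariate(supra[has_fu], ctrl)
                row.update({"control_or": lr["or"], "control_or_lo": lr["ci95"][0],
                            "control_or_hi": lr["ci95"][1], "control_p": lr["p"],
                            "separation": lr["separation"]})
                if not lr["separation"]:
                    control_ps[name] = {"p": lr["p"]}
            except SirtDoseError:
                pass
        try:
            sv = survival_suite(
                supra,
                np.array([r.os_months for r in analyzed]),
                np.array([r.death_observed for r in analyzed]),
            )
            row.update({
                "os_hr": sv["cox"]["hr"], "os_hr_lo": sv["cox"]["ci95"][0],
                "os_hr_hi": sv["cox"]["ci95"][1], "os_p": sv["cox"]["p"],
                "logrank_p": sv["logrank_p"],
                "km_median_infra": sv["km_median"]["inframedian"],
                "km_median_supra": sv["km_median"]["supramedian"],
            })
            os_ps[name] = {"p": sv["cox"]["p"]}
            for grp, med in sv["km_median"].items():
                km_rows.append({"metric": name, "group": grp, "km_median": med})
        except SirtDoseError:
            pass
        pred_rows.append(row)
    pd.DataFrame(pred_rows).to_csv(out / "predictors.csv", index=False)
    pd.DataFrame(km_rows).to_csv(out / "km_medians.csv", index=False)

    gate = {
        "tumor_control": multivariate_gate(
            control_ps, config.alpha, list(config.redundant_pairs)),
        "overall_survival": multivariate_gate(
            os_ps, config.alpha, list(config.redundant_pairs)),
    }

    manifest = _jsonable({
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_excluded_by_qa": n_excluded,
        "multivariate_gate": gate,
        "cohort_manifest": cohort.manifest,
        "runtime_s": time.time() - t0,
    })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline finished in %.1f s -> %s", time.time() - t0, out)
    return out
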