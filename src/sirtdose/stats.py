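"""Outcome statistics: agreement, dichotomization, tumor control, survival.

The statistical layer mirrors a standard radioembolization outcome
analysis.  Paired pre-/post-treatment dose metrics are compared with
Spearman rank correlation, the Wilcoxon signed-rank test and
Bland-Altman analysis.  Each dose metric is then dichotomized at the
*per-microsphere-type* median (resin and glass patients receive very
different absorbed-dose scales, so a pooled median would confound sphere
type with dose).  Supramedian status enters a univariate logistic model
for tumor control at 6 months and Kaplan-Meier / Cox models for overall
survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

SPHERE_TYPES = ("resin", "glass")


@dataclass
class PatientRecord:
    """One patient's treatment, dose metrics and outcomes.

    ``metrics`` maps metric names (``Dm-Pre-C_MRI``, ``TNR-Post-C_MRI``,
    ...) to values.  ``tumor_control_6mo`` is None when follow-up was too
    short to assess response; such patients are excluded listwise from
    the tumor-control analysis only.
    """

    id: str
    sphere_type: str
    injected_gbq: float
    metrics: dict[str, float] = field(default_factory=dict)
    tumor_control_6mo: bool | None = None
    os_months: float = 0.0
    death_observed: bool = False

    def __post_init__(self) -> None:
        if self.sphere_type not in SPHERE_TYPES:
            raise ParameterError(
                f"sphere_type must be one of {SPHERE_TYPES}, got {self.sphere_type!r}"
            )
        if self.os_months < 0:
            raise ParameterError("overall survival must be nonnegative")


@dataclass(frozen=True)
class DichotomizedMetric:
    """Supramedian/inframedian labels for one metric, per sphere type."""

    metric: str
    labels: dict[str, str]          # patient id -> "inframedian" | "supramedian"
    medians: dict[str, float]       # sphere type -> median used

    def supramedian(self, patient_id: str) -> bool:
        return self.labels[patient_id] == "supramedian"


# ---------------------------------------------------------------------------
# Agreement between paired measurements
# ---------------------------------------------------------------------------

def agreement_suite(pre: np.ndarray, post: np.ndarray) -> dict:
    """Pre- vs post-treatment agreement for one paired dose metric.

    Returns Spearman rho and p (tie-corrected ranks), the two-sided
    Wilcoxon signed-rank p, and the Bland-Altman summary: mean difference
    (post - pre) with its t-based 95% confidence interval and limits of
    agreement (mean +/- 1.96 SD).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 3:
        raise InsufficientDataError(f"agreement analysis needs >= 3 pairs, got {n}")
    rho, rho_p = sps.spearmanr(pre, post)
    diff = post - pre
    if np.allclose(diff, 0.0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(sps.wilcoxon(pre, post, alternative="two-sided").pvalue)
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return {
        "n": int(n),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "wilcoxon_p": float(wilcoxon_p),
        "bland_altman": {
            "mean_diff": mean_diff,
            "ci95": (mean_diff - tcrit * sem, mean_diff + tcrit * sem),
            "loa": (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd),
        },
    }


# ---------------------------------------------------------------------------
# Median dichotomization (stratified by sphere type)
# ---------------------------------------------------------------------------

def dichotomize(records: list[PatientRecord], metric: str) -> DichotomizedMetric:
    """Split patients at the per-sphere-type median of ``metric``.

    The median is computed within each sphere type separately; a patient
    is labelled supramedian iff its value is strictly above its own
    type's median (values exactly at the median are inframedian).
    Labels depend only on the value sets, never on patient order.
    """
    by_type: dict[str, list[tuple[str, float]]] = {t: [] for t in SPHERE_TYPES}
    for r in records:
        v = r.metrics.get(metric)
        if v is not None and np.isfinite(v):
            by_type[r.sphere_type].append((r.id, float(v)))
    present = {t: vals for t, vals in by_type.items() if vals}
    if not present:
        raise InsufficientDataError(f"metric {metric!r} missing for every patient")
    for t, vals in present.items():
        if len(vals) < 2:
            raise InsufficientDataError(
                f"metric {metric!r}: need >= 2 {t} patients, got {len(vals)}"
            )
    medians = {t: float(np.median([v for _, v in vals])) for t, vals in present.items()}
    labels = {}
    for t, vals in present.items():
        for pid, v in vals:
            labels[pid] = "supramedian" if v > medians[t] else "inframedian"
    return DichotomizedMetric(metric=metric, labels=labels, medians=medians)


# ---------------------------------------------------------------------------
# Tumor control: univariate logistic regression
# ---------------------------------------------------------------------------

def logistic_univariate(exposed: np.ndarray, outcome: np.ndarray) -> dict:
    """Odds ratio for a binary covariate by maximum-likelihood logistic fit.

    For a binary covariate the ML odds ratio equals the 2x2 cross-product
    ratio ``ad/bc``; the Wald 95% CI is computed on the log odds ratio.
    A zero cell (complete or quasi-separation) is flagged and the CI
    reported as unbounded.
    """
    exposed = np.asarray(exposed, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    if exposed.shape != outcome.shape:
        raise ParameterError("covariate and outcome must have equal length")
    if exposed.all() or (~exposed).all() or outcome.all() or (~outcome).all():
        raise InsufficientDataError(
            "logistic fit needs both covariate classes and both outcomes present"
        )
    a = int((exposed & outcome).sum())       # exposed, event
    b = int((exposed & ~outcome).sum())
    c = int((~exposed & outcome).sum())
    d = int((~exposed & ~outcome).sum())
    if min(a, b, c, d) == 0:
        return {
            "or": np.inf if b * c == 0 else 0.0,
            "ci95": (0.0, np.inf),
            "p": np.nan,
            "separation": True,
            "table": (a, b, c, d),
        }
    import statsmodels.api as sm

    x = sm.add_constant(exposed.astype(float))
    fit = sm.Logit(outcome.astype(int), x).fit(disp=0)
    log_or = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    return {
        "or": float(np.exp(log_or)),
        "ci95": (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))),
        "p": p,
        "separation": False,
        "table": (a, b, c, d),
    }


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier, log-rank, Cox
# ---------------------------------------------------------------------------

def km_median(times: np.ndarray, events: np.ndarray) -> float:
    """Kaplan-Meier median: smallest time with survival <= 0.5.

    Returns ``inf`` when the survival curve never reaches 0.5.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return float(kmf.median_survival_time_)


def survival_suite(
    group: np.ndarray,
    os_months: np.ndarray,
    death_observed: np.ndarray,
) -> dict:
    """Two-group survival comparison: KM medians, log-rank, univariate Cox.

    ``group`` is a boolean supramedian indicator.  The Cox model uses
    Breslow tie handling; the reported hazard ratio is for supramedian
    versus inframedian, with Wald 95% CI and two-sided p.
    """
    group = np.asarray(group, dtype=bool)
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(death_observed, dtype=bool)
    if group.all() or (~group).all():
        raise InsufficientDataError("survival comparison needs two nonempty groups")
    medians = {}
    flags = []
    for name, sel in (("inframedian", ~group), ("supramedian", group)):
        if e[sel].sum() == 0:
            medians[name] = np.inf
            flags.append(f"no events in {name} group; median undefined")
        else:
            medians[name] = km_median(t[sel], e[sel])
    lr = logrank_test(t[group], t[~group], e[group], e[~group])
    df = pd.DataFrame({"T": t, "E": e.astype(int), "supra": group.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E", show_progress=False)
    hr = float(np.exp(cph.params_["supra"]))
    se = float(cph.standard_errors_["supra"])
    log_hr = float(cph.params_["supra"])
    return {
        "km_median": medians,
        "logrank_p": float(lr.p_value),
        "cox": {
            "hr": hr,
            "ci95": (float(np.exp(log_hr - 1.96 * se)),
                     float(np.exp(log_hr + 1.96 * se))),
            "p": float(cph.summary.loc["supra", "p"]),
        },
        "flags": flags,
    }


def multivariate_gate(
    univariate: dict[str, dict],
    alpha: float = 0.05,
    redundant_pairs: list[tuple[str, str]] | None = None,
) -> list[str]:
    """Select covariates for a multivariate model.

    Keeps covariates with univariate p strictly below ``alpha``; for each
    configured redundant pair with both members selected, only the first
    (the designated representative) is retained.  An empty selection is
    logged and the multivariate step should be skipped by the caller.
    """
    selected = [name for name, res in univariate.items()
                if np.isfinite(res.get("p", np.nan)) and res["p"] < alpha]
    for keep, drop in (redundant_pairs or []):
        if keep in selected and drop in selected:
            selected.remove(drop)
    if not selected:
        logger.info("no covariate passed the univariate gate (alpha=%g); "
                    "multivariate step skipped", alpha)
    return selected


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into a tidy cohort table (one row/patient)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sphere_type": r.sphere_type,
            "injected_gbq": r.injected_gbq,
            "tumor_control_6mo": r.tumor_control_6mo,
            "os_months": r.os_months,
            "death_observed": r.death_observed,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
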