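"""Cumulative dose-volume histograms and the derived metrics Dm, D70, TNR.

The cumulative DVH of a contour maps each dose level ``d`` to the
fraction of the contour volume receiving at least ``d`` Gy.  From it we
read the mean absorbed dose Dm (which equals the integral of the curve)
and D70, the minimal dose covering the best-irradiated 70% of the
contour.  TNR, the tumor-to-normal-liver uptake ratio, is computed from
raw counts and contour volumes and is invariant to the count scale.

The exact sort-based curve is the reference everywhere; fixed-width
binning (default 0.1 Gy) exists only for export and plotting, so D70 is
never sensitive to a bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContourError, ParameterError
from .volumes import ContourMask, CountVolume, DoseMap, require_aligned

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve.

    ``dose_gy`` is an increasing grid of minimal-dose values starting at
    0; ``volume_fraction[i]`` is the fraction of the contour volume
    receiving at least ``dose_gy[i]``, so the curve starts at 1 and is
    non-increasing.  Between listed points the curve is the step function
    of the underlying voxel doses: ``volume_fraction[i]`` holds on the
    half-open interval ``(dose_gy[i-1], dose_gy[i]]``.
    """

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if d.ndim != 1 or d.shape != v.shape or d.size == 0:
            raise ParameterError("DVH curve needs matching 1D dose and fraction arrays")
        if np.any(np.diff(d) <= 0):
            raise ParameterError("DVH dose grid must be strictly increasing")
        if np.any(np.diff(v) > 1e-12):
            raise ParameterError("DVH volume fraction must be non-increasing")
        if not np.isclose(v[0], 1.0):
            raise ParameterError("DVH must start at volume fraction 1")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume_fraction", v)

    def integral(self) -> float:
        """Area under the curve; equals the mean dose for the exact curve."""
        d, v = self.dose_gy, self.volume_fraction
        # V is constant on (d_i, d_{i+1}] at the level V(d_{i+1})
        return float(np.sum(np.diff(d) * v[1:]) + d[0] * v[0])

    def fraction_at(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose`` Gy (step lookup)."""
        d, v = self.dose_gy, self.volume_fraction
        if dose <= d[0]:
            return float(v[0])
        i = int(np.searchsorted(d, dose, side="left"))
        return float(v[i]) if i < d.size else 0.0


def cumulative_dvh(
    dose: DoseMap,
    contour: ContourMask,
    bin_width_gy: float | None = None,
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over ``contour``.

    With ``bin_width_gy=None`` (default) the exact sort-based curve over
    the unique voxel doses is returned; a positive bin width instead
    samples the fraction on a fixed 0..max dose grid for export.
    """
    require_aligned(dose.grid, contour.grid, "dose and contour")
    if contour.n_voxels == 0:
        raise ContourError("cannot compute a DVH over an empty contour")
    vals = np.sort(dose.values[contour.values.astype(bool)])
    n = vals.size
    if bin_width_gy is None:
        uniq = np.unique(vals)
        # fraction of voxels with dose >= u, for each unique dose u
        frac = 1.0 - np.searchsorted(vals, uniq, side="left") / n
        if uniq[0] > 0.0:
            uniq = np.concatenate(([0.0], uniq))
            frac = np.concatenate(([1.0], frac))
        return DVHCurve(uniq, frac)
    if bin_width_gy <= 0:
        raise ParameterError(f"bin width must be positive, got {bin_width_gy}")
    dmax = float(vals[-1])
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / n
    return DVHCurve(edges, frac)


def mean_dose(dose: DoseMap, contour: ContourMask) -> float:
    """Mean absorbed dose Dm (Gy) over a nonempty contour."""
    require_aligned(dose.grid, contour.grid, "dose and contour")
    sel = contour.values.astype(bool)
    if not sel.any():
        raise ContourError("mean dose over an empty contour is undefined")
    return float(dose.values[sel].mean())


def d_percent(dvh: DVHCurve, percent: float = 70.0) -> float:
    """D_x: the minimal dose received by the best-covered x% of the volume.

    Reads the cumulative curve as the step function it is: the result is
    the largest listed dose whose volume fraction still reaches
    ``percent/100``.  On a uniform dose this returns that dose exactly;
    it is non-increasing in ``percent``.
    """
    if not 0.0 < percent < 100.0:
        raise ParameterError(f"percent must be in (0, 100), got {percent}")
    target = percent / 100.0
    qualifying = dvh.volume_fraction >= target - 1e-12
    if not qualifying.any():
        raise ParameterError("malformed DVH: no dose level covers the requested fraction")
    return float(dvh.dose_gy[np.nonzero(qualifying)[0][-1]])


def tnr(
    counts: CountVolume,
    tumor: ContourMask,
    normal_liver: ContourMask,
) -> float:
    """Tumor-to-normal-liver activity-concentration ratio.

    ``(CNTS_tum / V_tum) / (CNTS_NL / V_NL)`` with contour volumes in mL;
    invariant to rescaling the counts.  Intended for anatomy-based
    (radiologic) contours, where tumor and normal liver are disjoint.
    """
    require_aligned(counts.grid, tumor.grid, "counts and tumor")
    require_aligned(counts.grid, normal_liver.grid, "counts and normal liver")
    if tumor.n_voxels == 0 or normal_liver.n_voxels == 0:
        raise ContourError("TNR requires nonempty tumor and normal-liver contours")
    if np.any(tumor.values & normal_liver.values):
        raise ContourError("tumor and normal-liver contours overlap")
    cnts_tum = float(counts.values[tumor.values.astype(bool)].sum())
    cnts_nl = float(counts.values[normal_liver.values.astype(bool)].sum())
    if cnts_nl <= 0.0:
        raise ContourError("normal liver contains zero counts; TNR undefined")
    # both contours share one grid, so the voxel volume cancels from the
    # concentration ratio; using voxel counts avoids the extra rounding
    conc_tum = cnts_tum / tumor.n_voxels
    conc_nl = cnts_nl / normal_liver.n_voxels
    return conc_tum / conc_nl


def tumor_burden(tumor_ml: float, liver_ml: float) -> float:
    """Tumor burden as a percentage of the liver volume."""
    if tumor_ml <= 0 or liver_ml <= 0:
        raise ParameterError("volumes must be positive")
    if tumor_ml > liver_ml:
        raise ParameterError(
            f"tumor volume {tumor_ml} mL exceeds liver volume {liver_ml} mL"
        )
    return 100.0 * tumor_ml / liver_ml


@dataclass(frozen=True)
class DoseMetrics:
    """Bundle of the three dose metrics for one contour.

    ``name`` follows the self-describing scheme metric-timepoint-method,
    e.g. ``Dm-Pre-C_MRI`` or ``D70-Post-C_PET``; TNR is only defined for
    anatomy-based contours.
    """

    name: str
    dm_gy: float
    d70_gy: float
    volume_ml: float
    tnr: float | None = None


def contour_metrics(
    dose: DoseMap,
    contour: ContourMask,
    name: str,
    counts: CountVolume | None = None,
    normal_liver_mask: ContourMask | None = None,
    percent: float = 70.0,
) -> DoseMetrics:
    """Compute Dm, D_x and (if counts and normal liver given) TNR."""
    dvh = cumulative_dvh(dose, contour)
    ratio = None
    if counts is not None and normal_liver_mask is not None:
        ratio = tnr(counts, contour, normal_liver_mask)
    return DoseMetrics(
        name=name,
        dm_gy=mean_dose(dose, contour),
        d70_gy=d_percent(dvh, percent),
        volume_ml=contour.volume_ml,
        tnr=ratio,
    )
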