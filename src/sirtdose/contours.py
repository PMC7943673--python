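"""Contour construction and segmentation quality assurance.

Two contour families feed the dosimetry: anatomy-derived masks (liver and
tumor drawn on morphological imaging, transferred to the emission grid)
and scintigraphic threshold targets (all voxels above a fixed fraction of
the maximum uptake inside a volume of interest around the liver).  This
module builds both, derives the normal-liver remainder, and computes the
registration QA statistics (Dice overlap against a pass threshold, and
the inter-operator root-mean-square coefficient of variation of contour
volumes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContourError, ParameterError
from .volumes import ContourMask, CountVolume, require_aligned

logger = logging.getLogger(__name__)

#: Default uptake threshold: voxels above 10% of the VOI maximum.
DEFAULT_THRESHOLD_FRACTION = 0.10

#: Minimum accepted Dice overlap for a registered contour pair.
DEFAULT_DICE_THRESHOLD = 0.85


@dataclass
class ContourSet:
    """Liver / tumor / normal-liver masks from one contouring method.

    ``provenance`` tags the method, e.g. ``"C_MRI"`` for anatomy-based
    contours or ``"C_SPECT"`` / ``"C_PET"`` for threshold-based targets.

    Invariants enforced at construction: tumor is a subset of the liver
    and normal liver is the exact set difference, so the tumor and
    normal-liver masks partition the liver.
    """

    liver: ContourMask
    tumor: ContourMask
    normal: ContourMask
    provenance: str = "C_MRI"
    target_threshold: ContourMask | None = None

    def __post_init__(self) -> None:
        require_aligned(self.liver.grid, self.tumor.grid, "liver/tumor masks")
        require_aligned(self.liver.grid, self.normal.grid, "liver/normal masks")
        if np.any(self.tumor.values & ~self.liver.values):
            raise ContourError("tumor mask extends outside the liver mask")
        if np.any(self.tumor.values & self.normal.values):
            raise ContourError("tumor and normal-liver masks overlap")
        expected = self.liver.values & ~self.tumor.values
        if not np.array_equal(self.normal.values, expected):
            raise ContourError("normal liver is not the liver \\ tumor set difference")

    @classmethod
    def from_liver_tumor(
        cls,
        liver: ContourMask,
        tumor: ContourMask,
        provenance: str = "C_MRI",
        target_threshold: ContourMask | None = None,
    ) -> "ContourSet":
        nl = normal_liver(liver, tumor)
        return cls(liver, tumor, nl, provenance=provenance,
                   target_threshold=target_threshold)


def threshold_contour(
    counts: CountVolume,
    voi: ContourMask,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    strict: bool = True,
) -> ContourMask:
    """Percentage-of-maximum threshold segmentation within a VOI.

    Selects the voxels of ``voi`` whose counts exceed ``fraction`` times
    the maximum count *inside the VOI* (not the global image maximum, so
    extrahepatic hot spots cannot distort the threshold).  The result is
    invariant under any positive rescaling of the counts.

    Parameters
    ----------
    counts
        Emission count volume.
    voi
        Volume of interest surrounding the liver; must be nonempty.
    fraction
        Threshold level in (0, 1); default 0.10 (10% of maximum).
    strict
        If True (default) voxels exactly at the threshold are excluded
        (comparison ``>``); if False they are included (``>=``).
    """
    require_aligned(counts.grid, voi.grid, "counts and VOI")
    if voi.n_voxels == 0:
        raise ContourError("threshold contouring requires a nonempty VOI")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"threshold fraction must be in (0, 1), got {fraction}")
    inside = voi.values.astype(bool)
    vmax = float(counts.values[inside].max())
    if vmax <= 0.0:
        warnings.warn("all counts in the VOI are zero; threshold contour is empty",
                      stacklevel=2)
        return ContourMask(counts.grid, np.zeros(counts.grid.shape, dtype=np.uint8),
                           label="target_threshold")
    level = fraction * vmax
    if strict:
        sel = counts.values > level
    else:
        sel = counts.values >= level
    return ContourMask(counts.grid, (sel & inside).astype(np.uint8),
                       label="target_threshold")


def normal_liver(
    liver: ContourMask,
    tumor: ContourMask,
    on_outside: str = "clip",
) -> ContourMask:
    """Healthy-liver mask: liver voxels not in the tumor.

    When the tumor extends outside the liver, ``on_outside`` selects the
    policy: ``"clip"`` (default) ignores the outside voxels with a
    warning; ``"error"`` raises :class:`ContourError`.
    """
    require_aligned(liver.grid, tumor.grid, "liver and tumor masks")
    outside = int((tumor.values & ~liver.values).sum())
    if outside:
        msg = f"{outside} tumor voxel(s) lie outside the liver mask"
        if on_outside == "error":
            raise ContourError(msg)
        warnings.warn(msg + "; clipping to the liver", stacklevel=2)
    return ContourMask(liver.grid, (liver.values & ~tumor.values).astype(np.uint8),
                       label="normal_liver")


def dice(a: ContourMask, b: ContourMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two aligned binary masks."""
    require_aligned(a.grid, b.grid, "masks for Dice")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ContourError("Dice undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def registration_qa(
    dice_value: float,
    threshold: float = DEFAULT_DICE_THRESHOLD,
    patient_id: str | None = None,
) -> bool:
    """Accept a registered contour pair iff its Dice >= threshold (inclusive).

    Failures are logged with the patient id so a cohort run can report
    which registrations were rejected.
    """
    if not 0.0 <= dice_value <= 1.0:
        raise ParameterError(f"Dice must lie in [0, 1], got {dice_value}")
    ok = dice_value >= threshold
    if not ok:
        logger.warning(
            "registration QA failed%s: Dice %.3f < %.2f",
            f" for patient {patient_id}" if patient_id else "",
            dice_value, threshold,
        )
    return ok


def interoperator_rms_cv(volume_pairs: Iterable[Sequence[float]]) -> float:
    """Inter-operator reproducibility of contour volumes, in percent.

    For each pair of volumes delineated by two operators the coefficient
    of variation is the sample (n-1) standard deviation over the mean;
    for two values this reduces to ``|vA - vB| / (sqrt(2) * mean)``.  The
    summary statistic is the root mean square of the per-pair CVs, x100.
    """
    pairs = [tuple(float(v) for v in p) for p in volume_pairs]
    if not pairs:
        raise ParameterError("at least one volume pair is required")
    cvs = []
    for p in pairs:
        if len(p) < 2:
            raise ParameterError(f"need >= 2 volumes per pair, got {p}")
        if any(v <= 0 for v in p):
            raise ParameterError(f"volumes must be positive, got {p}")
        arr = np.asarray(p)
        cvs.append(arr.std(ddof=1) / arr.mean())
    return float(np.sqrt(np.mean(np.square(cvs))) * 100.0)
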