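"""Normal-tissue dose metrics.

Two scalars summarize normal-tissue exposure in the study: the mean dose
inside the Eval_Normal ROI (reported in cGy) and the "intersecting
volume" -- the Eval_Normal volume receiving at least 50% of the 20 Gy
prescription (>= 10.0 Gy), in cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, RoiMask
from .simulate import PRESCRIPTION_GY

__all__ = ["NormalTissueMetrics", "mean_dose", "intersecting_volume",
           "DEFAULT_THRESHOLD_GY"]

#: 50% of the 20.0 Gy prescription
DEFAULT_THRESHOLD_GY = PRESCRIPTION_GY / 2.0


@dataclass(frozen=True)
class NormalTissueMetrics:
    mean_dose_cgy: float
    intersecting_volume_cm3: float
    threshold_dose_gy: float = DEFAULT_THRESHOLD_GY


def mean_dose(dose: DoseGrid, mask: RoiMask) -> float:
    """Arithmetic mean dose over the masked voxels, in cGy."""
    if dose.grid != mask.grid:
        raise ValueError("mask grid differs from dose grid")
    if not mask.mask.any():
        raise ValueError(f"mask {mask.name!r} is empty")
    return float(dose.values[mask.mask].mean()) * 100.0


def intersecting_volume(dose: DoseGrid, mask: RoiMask,
                        threshold_gy: float = DEFAULT_THRESHOLD_GY) -> float:
    """Masked volume (cm^3) receiving >= threshold (inclusive)."""
    if threshold_gy <= 0:
        raise ValueError("threshold must be > 0")
    if dose.grid != mask.grid:
        raise ValueError("mask grid differs from dose grid")
    n = int((mask.mask & (dose.values >= threshold_gy)).sum())
    return n * dose.grid.voxel_volume_cm3


def evaluate(dose: DoseGrid, eval_normal: RoiMask,
             threshold_gy: float = DEFAULT_THRESHOLD_GY) -> NormalTissueMetrics:
    """Both normal-tissue metrics for one dose field."""
    return NormalTissueMetrics(
        mean_dose_cgy=mean_dose(dose, eval_normal),
        intersecting_volume_cm3=intersecting_volume(dose, eval_normal,
                                                    threshold_gy),
        threshold_dose_gy=threshold_gy,
    )
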