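"""Cumulative DVHs and the classical lung dosimetric factors (Vx, MLD).

The dose comparator for ``V_x`` is ``>= x`` so that ``V_0`` is 100% of the
ROI volume; a strict ``>`` comparator is available via ``inclusive=False``.
``v_x`` counts voxels directly and never interpolates the DVH, so the DVH bin
width has no effect on reported factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DoseGrid,
    EmptyRoiError,
    FeatureTable,
    ROI_SUFFIX,
    RoiMask,
    in_mask_doses,
)

#: the factor set computed per lung volume
DOSIMETRIC_FACTORS = ("V5", "V10", "V15", "V20", "MLD")


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative dose-volume histogram.

    ``volume_fraction[k]`` is the fraction of ROI volume receiving at least
    ``dose_edges[k]`` Gy; it starts at 1 for a zero first edge and is
    non-increasing.
    """

    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def v_at(self, x: float) -> float:
        """Volume fraction at the DVH edge closest to ``x`` (bin-aligned)."""
        idx = int(np.argmin(np.abs(self.dose_edges - x)))
        return float(self.volume_fraction[idx])


def compute_dvh(dose: DoseGrid, mask: RoiMask, bin_width: float = 0.1) -> CumulativeDVH:
    """Cumulative DVH on edges 0, w, 2w, ... covering the in-mask dose range."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.sort(in_mask_doses(dose, mask))
    n_edges = int(np.floor(d[-1] / bin_width)) + 1
    edges = np.arange(n_edges + 1) * bin_width
    # fraction of voxels with dose >= edge, via position in the sorted vector
    below = np.searchsorted(d, edges, side="left")
    frac = (d.size - below) / d.size
    return CumulativeDVH(edges, frac)


def v_x(dose: DoseGrid, mask: RoiMask, x: float, inclusive: bool = True) -> float:
    """Percent of ROI volume receiving at least (or above) ``x`` Gy."""
    d = in_mask_doses(dose, mask)
    hit = d >= x if inclusive else d > x
    return 100.0 * float(hit.mean())


def mean_lung_dose(dose: DoseGrid, mask: RoiMask) -> float:
    """Arithmetic mean of in-mask voxel doses (Gy)."""
    return float(in_mask_doses(dose, mask).mean())


def lung_set(left: RoiMask, right: RoiMask, tumor_side: str) -> tuple[RoiMask, RoiMask, RoiMask]:
    """Assign ipsilateral/contralateral/total roles from tumor laterality."""
    if tumor_side not in ("left", "right"):
        raise ValueError(f"tumor_side must be 'left' or 'right', got {tumor_side!r}")
    if left.shape != right.shape:
        raise ValueError("left/right masks have different shapes")
    if np.any(left.values & right.values):
        raise ValueError("left and right lung masks overlap")
    ipsi, contra = (left, right) if tumor_side == "left" else (right, left)
    total = RoiMask(left.values | right.values, role="total",
                    spacing=left.spacing, origin=left.origin)
    return ipsi.with_role("ipsilateral"), contra.with_role("contralateral"), total


def dosimetric_factor_row(dose: DoseGrid, masks: dict[str, RoiMask]) -> dict[str, float]:
    """The 15 Vx/MLD factors (5 factors x 3 lung volumes) for one patient."""
    row: dict[str, float] = {}
    for role in ("ipsilateral", "contralateral", "total"):
        mask = masks[role]
        if mask.count == 0:
            raise EmptyRoiError(f"ROI {role!r} is empty")
        suffix = ROI_SUFFIX[role]
        for x in (5, 10, 15, 20):
            row[f"V{x}_{suffix}"] = v_x(dose, mask, float(x))
        row[f"MLD_{suffix}"] = mean_lung_dose(dose, mask)
    return row


def dosimetric_factor_table(
    cohort: list[tuple[str, DoseGrid, dict[str, RoiMask]]],
    outcome: pd.Series | None = None,
) -> FeatureTable:
    """Dosimetric factors for a cohort of (patient_id, dose, role->mask)."""
    rows = {}
    for pid, dose, masks in cohort:
        try:
            rows[pid] = dosimetric_factor_row(dose, masks)
        except EmptyRoiError as exc:
            raise EmptyRoiError(f"patient {pid}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureTable(df, outcome=outcome)
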