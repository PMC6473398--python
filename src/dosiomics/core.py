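"""Core containers shared by every pipeline stage.

Arrays are indexed ``(z, y, x)`` internally; ``spacing`` is ``(dx, dy, dz)``
in millimetres and ``origin`` is the patient-space position ``(x, y, z)`` of
the centre of voxel ``[0, 0, 0]``.  All dose values are absorbed dose in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


class DosiomicsError(Exception):
    """Base class for all package errors."""


class FormatError(DosiomicsError):
    """A file does not conform to the expected on-disk format."""


class AlignmentError(DosiomicsError):
    """Mask and dose grid geometries disagree beyond tolerance."""


class EmptyRoiError(DosiomicsError):
    """An operation that needs in-mask voxels received an empty ROI."""


class DegenerateOutcomeError(DosiomicsError):
    """Outcome vector contains a single class."""


class UndefinedCorrelationError(DosiomicsError):
    """Correlation of a constant vector is undefined."""


class NoAdmissiblePairError(DosiomicsError):
    """Every candidate feature pair was excluded by the correlation gate."""


ROI_ROLES = ("ipsilateral", "contralateral", "total")

#: short column suffixes used throughout feature tables
ROI_SUFFIX = {"ipsilateral": "ipsi", "contralateral": "contra", "total": "total"}

GEOMETRY_TOL = 1e-3  # mm, for spacing/origin agreement checks


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absorbed-dose distribution with grid geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise FormatError(f"dose grid must be 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("dose grid contains non-finite values")
        if np.any(v < 0):
            raise FormatError("dose grid contains negative dose")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class RoiMask:
    """A boolean region-of-interest mask aligned to a :class:`DoseGrid`."""

    values: np.ndarray
    role: str = "total"
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {v.shape}")
        object.__setattr__(self, "values", v.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def with_role(self, role: str) -> "RoiMask":
        if role not in ROI_ROLES and role not in ("left", "right"):
            raise ValueError(f"unknown ROI role {role!r}")
        return replace(self, role=role)


def check_aligned(dose: DoseGrid, mask: RoiMask) -> None:
    """Raise :class:`AlignmentError` unless mask and dose share a grid."""
    if dose.shape != mask.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match dose grid shape {dose.shape}"
        )
    ds, ms = np.asarray(dose.spacing), np.asarray(mask.spacing)
    do, mo = np.asarray(dose.origin), np.asarray(mask.origin)
    if np.any(np.abs(ds - ms) > GEOMETRY_TOL) or np.any(np.abs(do - mo) > GEOMETRY_TOL):
        raise AlignmentError(
            f"mask geometry (spacing={mask.spacing}, origin={mask.origin}) does not "
            f"match dose geometry (spacing={dose.spacing}, origin={dose.origin})"
        )


def in_mask_doses(dose: DoseGrid, mask: RoiMask) -> np.ndarray:
    """Return the 1D vector of in-mask voxel doses, validating alignment."""
    check_aligned(dose, mask)
    if mask.count == 0:
        raise EmptyRoiError(f"ROI {mask.role!r} contains no voxels")
    return dose.values[mask.values]


@dataclass
class FeatureTable:
    """Patients x named-features table with an optional binary outcome.

    ``features`` is indexed by patient id.  ``normalized`` records whether
    columns have been z-scored; the normalisation parameters (per-column mean
    and sample standard deviation) are kept in ``norm_params`` so that the
    identical transform can be re-applied to new rows.
    """

    features: pd.DataFrame
    outcome: Optional[pd.Series] = None
    normalized: bool = False
    norm_params: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            bad = self.features.columns[self.features.isna().any()].tolist()
            raise FormatError(f"feature table has missing values in columns {bad}")
        if self.outcome is not None:
            self.outcome = self.outcome.reindex(self.features.index)
            vals = set(pd.unique(self.outcome.dropna()))
            if not vals <= {0, 1}:
                raise FormatError(f"outcome must be binary 0/1, got values {sorted(vals)}")
            self.outcome = self.outcome.astype(int)

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.features[columns].copy(),
            outcome=None if self.outcome is None else self.outcome.copy(),
            normalized=self.normalized,
            norm_params=None
            if self.norm_params is None
            else self.norm_params.loc[columns].copy(),
        )

    def to_csv(self, path) -> None:
        df = self.features.copy()
        if self.outcome is not None:
            df["outcome"] = self.outcome
        df.to_csv(path, index=True, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, outcome_column: str = "outcome") -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        outcome = None
        if outcome_column in df.columns:
            outcome = df.pop(outcome_column)
        return cls(df, outcome=outcome)


def concat_feature_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of tables sharing the same patients."""
    idx = tables[0].features.index
    for t in tables[1:]:
        if not t.features.index.equals(idx):
            raise FormatError("feature tables have mismatched patient indices")
    outcome = next((t.outcome for t in tables if t.outcome is not None), None)
    return FeatureTable(pd.concat([t.features for t in tables], axis=1), outcome=outcome)
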