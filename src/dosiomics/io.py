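"""File I/O: DICOM RT Dose, RT Structure Set contours, and NIfTI volumes.

Conventions
-----------
Arrays are ``(z, y, x)``; NIfTI files are written in ``(x, y, z)`` order with
a diagonal affine built from ``spacing`` and ``origin`` (RAS, no rotation).
Masks must share the dose grid geometry: a mismatch beyond 1e-3 mm raises an
:class:`~dosiomics.core.AlignmentError` rather than silently resampling,
because texture features are sensitive to the sampling grid.  An explicit
nearest-neighbour resample is available as an opt-in
(:func:`resample_mask_nearest`).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from . import _dicom
from .core import AlignmentError, DoseGrid, FormatError, GEOMETRY_TOL, RoiMask

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

_TAG = {
    "Rows": (0x0028, 0x0010),
    "Columns": (0x0028, 0x0011),
    "NumberOfFrames": (0x0028, 0x0008),
    "PixelSpacing": (0x0028, 0x0030),
    "BitsAllocated": (0x0028, 0x0100),
    "PixelRepresentation": (0x0028, 0x0103),
    "ImagePositionPatient": (0x0020, 0x0032),
    "GridFrameOffsetVector": (0x3004, 0x000C),
    "DoseGridScaling": (0x3004, 0x000E),
    "PixelData": (0x7FE0, 0x0010),
    "StructureSetROISequence": (0x3006, 0x0020),
    "ROIContourSequence": (0x3006, 0x0039),
    "ROINumber": (0x3006, 0x0022),
    "ROIName": (0x3006, 0x0026),
    "ReferencedROINumber": (0x3006, 0x0084),
    "ContourSequence": (0x3006, 0x0040),
    "ContourGeometricType": (0x3006, 0x0042),
    "ContourData": (0x3006, 0x0050),
}


def _as_list(v):
    return list(v) if isinstance(v, (list, tuple)) else [v]


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (values in Gy)."""
    ds = _dicom.read_dicom(path)
    if _TAG["DoseGridScaling"] not in ds:
        raise FormatError("RT Dose file is missing DoseGridScaling (3004,000E)")
    scaling = float(ds[_TAG["DoseGridScaling"]])
    rows = int(ds[_TAG["Rows"]])
    cols = int(ds[_TAG["Columns"]])
    nframes = int(ds.get(_TAG["NumberOfFrames"], 1))
    if _TAG["GridFrameOffsetVector"] not in ds:
        raise FormatError("RT Dose file is missing GridFrameOffsetVector (3004,000C)")
    offsets = np.asarray(_as_list(ds[_TAG["GridFrameOffsetVector"]]), dtype=float)
    if len(offsets) != nframes:
        raise FormatError(
            f"GridFrameOffsetVector length {len(offsets)} != NumberOfFrames {nframes}"
        )
    if nframes > 1:
        steps = np.diff(offsets)
        if np.any(np.abs(steps - steps[0]) > 1e-6):
            raise FormatError("GridFrameOffsetVector (3004,000C) is not uniformly spaced")
        dz = float(steps[0])
    else:
        dz = float(ds.get((0x0018, 0x0050), 1.0))  # SliceThickness fallback
    py, px = [float(v) for v in _as_list(ds[_TAG["PixelSpacing"]])]  # row\col
    origin = tuple(float(v) for v in _as_list(ds[_TAG["ImagePositionPatient"]]))
    bits = int(ds.get(_TAG["BitsAllocated"], 32))
    raw = ds[_TAG["PixelData"]]
    dtype = {16: np.uint16, 32: np.uint32}.get(bits)
    if dtype is None:
        raise FormatError(f"unsupported BitsAllocated {bits}")
    stored = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"),
                           count=nframes * rows * cols)
    values = stored.reshape(nframes, rows, cols).astype(float) * scaling
    return DoseGrid(values, spacing=(px, py, dz),
                    origin=(origin[0], origin[1], origin[2] + offsets[0]))


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a :class:`DoseGrid` as DICOM RT Dose (32-bit, GY, PHYSICAL)."""
    dmax = float(grid.values.max())
    scaling = dmax / (2**31 - 1) if dmax > 0 else 1.0
    stored = np.round(grid.values / scaling).astype("<u4")
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.spacing
    offsets = [i * dz for i in range(nz)]
    elements = [
        ((0x0008, 0x0016), "UI", RTDOSE_SOP_CLASS),
        ((0x0008, 0x0060), "CS", "RTDOSE"),
        ((0x0020, 0x0032), "DS", list(grid.origin)),
        ((0x0020, 0x0037), "DS", [1, 0, 0, 0, 1, 0]),
        ((0x0028, 0x0002), "US", 1),
        ((0x0028, 0x0004), "CS", "MONOCHROME2"),
        ((0x0028, 0x0008), "IS", nz),
        ((0x0028, 0x0010), "US", ny),
        ((0x0028, 0x0011), "US", nx),
        ((0x0028, 0x0030), "DS", [dy, dx]),
        ((0x0028, 0x0100), "US", 32),
        ((0x0028, 0x0101), "US", 32),
        ((0x0028, 0x0102), "US", 31),
        ((0x0028, 0x0103), "US", 0),
        ((0x3004, 0x0002), "CS", "GY"),
        ((0x3004, 0x0004), "CS", "PHYSICAL"),
        ((0x3004, 0x000C), "DS", offsets),
        ((0x3004, 0x000E), "DS", [scaling]),
        ((0x7FE0, 0x0010), "OW", stored.tobytes()),
    ]
    _dicom.write_dicom(path, elements, RTDOSE_SOP_CLASS)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_mask(mask: RoiMask, path) -> None:
    """Write a mask as uint8 NIfTI, array stored ``(x, y, z)``."""
    data = np.transpose(mask.values.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(mask.spacing, mask.origin)), str(path))


def write_dose_nifti(grid: DoseGrid, path) -> None:
    # float64 so synthetic doses round-trip bit-exactly through disk
    data = np.transpose(grid.values.astype(np.float64), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(grid.spacing, grid.origin)), str(path))


def read_dose_nifti(path) -> DoseGrid:
    img = nib.load(str(path))
    aff = img.affine
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return DoseGrid(data, spacing=spacing, origin=origin)


def read_mask(path, role: str = "total", grid: DoseGrid | None = None) -> RoiMask:
    """Read a NIfTI mask; if ``grid`` is given, geometry must match it."""
    img = nib.load(str(path))
    aff = img.affine
    if np.any(np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))) > 1e-9):
        raise FormatError("mask NIfTI affine has rotation/shear; only axis-aligned supported")
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0)) > 0
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    mask = RoiMask(data, role=role, spacing=spacing, origin=origin)
    if grid is not None:
        if grid.shape != mask.shape or np.any(
            np.abs(np.asarray(grid.spacing) - np.asarray(spacing)) > GEOMETRY_TOL
        ) or np.any(np.abs(np.asarray(grid.origin) - np.asarray(origin)) > GEOMETRY_TOL):
            raise AlignmentError(
                f"mask geometry (shape={mask.shape}, spacing={spacing}, origin={origin}) "
                f"does not match dose geometry (shape={grid.shape}, "
                f"spacing={grid.spacing}, origin={grid.origin})"
            )
    return mask


def resample_mask_nearest(mask: RoiMask, grid: DoseGrid) -> RoiMask:
    """Explicit opt-in nearest-neighbour resample of a mask onto a dose grid."""
    nz, ny, nx = grid.shape
    out = np.zeros(grid.shape, dtype=bool)
    zi = np.round((grid.origin[2] + np.arange(nz) * grid.spacing[2] - mask.origin[2]) / mask.spacing[2]).astype(int)
    yi = np.round((grid.origin[1] + np.arange(ny) * grid.spacing[1] - mask.origin[1]) / mask.spacing[1]).astype(int)
    xi = np.round((grid.origin[0] + np.arange(nx) * grid.spacing[0] - mask.origin[0]) / mask.spacing[0]).astype(int)
    zv = (zi >= 0) & (zi < mask.shape[0])
    yv = (yi >= 0) & (yi < mask.shape[1])
    xv = (xi >= 0) & (xi < mask.shape[2])
    sub = mask.values[np.ix_(zi[zv], yi[yv], xi[xv])]
    out[np.ix_(zv, yv, xv)] = sub
    return RoiMask(out, role=mask.role, spacing=grid.spacing, origin=grid.origin)


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorised over points."""
    inside = np.zeros(px.shape, dtype=bool)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for k in range(len(poly)):
        crosses = (y0[k] > py) != (y1[k] > py)
        if not crosses.any():
            continue
        xint = (x1[k] - x0[k]) * (py - y0[k]) / (y1[k] - y0[k]) + x0[k]
        inside ^= crosses & (px < xint)
    return inside


def list_structures(rtstruct_path) -> list[str]:
    ds = _dicom.read_dicom(rtstruct_path)
    return [item.get(_TAG["ROIName"], "") for item in ds.get(_TAG["StructureSetROISequence"], [])]


def rasterize_contours(rtstruct_path, roi_name: str, grid: DoseGrid,
                       role: str = "total") -> RoiMask:
    """Rasterise RT Structure Set planar contours onto the dose grid.

    Each contour is assigned to the nearest grid plane in z and filled with an
    even-odd rule at voxel centres; multiple contours on one slice XOR
    (so holes work).
    """
    ds = _dicom.read_dicom(rtstruct_path)
    names = {}
    for item in ds.get(_TAG["StructureSetROISequence"], []):
        names[int(item[_TAG["ROINumber"]])] = item.get(_TAG["ROIName"], "")
    number = next((num for num, name in names.items() if name == roi_name), None)
    if number is None:
        raise KeyError(
            f"ROI {roi_name!r} not found; available: {sorted(names.values())}"
        )
    contours = []
    for item in ds.get(_TAG["ROIContourSequence"], []):
        if int(item.get(_TAG["ReferencedROINumber"], -1)) == number:
            contours = item.get(_TAG["ContourSequence"], [])
            break
    nz, ny, nx = grid.shape
    out = np.zeros(grid.shape, dtype=bool)
    xs = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    for contour in contours:
        gtype = contour.get(_TAG["ContourGeometricType"], "CLOSED_PLANAR")
        if gtype not in ("CLOSED_PLANAR", "CLOSEDPLANAR_XOR"):
            continue
        pts = np.asarray(_as_list(contour[_TAG["ContourData"]]), dtype=float).reshape(-1, 3)
        if len(pts) < 3:
            continue
        iz = int(round((float(pts[:, 2].mean()) - grid.origin[2]) / grid.spacing[2]))
        if iz < 0 or iz >= nz:
            continue
        out[iz] ^= _points_in_polygon(gx, gy, pts[:, :2])
    return RoiMask(out, role=role, spacing=grid.spacing, origin=grid.origin)
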