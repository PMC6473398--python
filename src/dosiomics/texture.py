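"""3D dose-texture features: gray-level co-occurrence and run-length matrices.

The in-mask dose is quantised to ``Ng`` equal-width gray levels (default 64,
over the in-mask dose range).  GLCMs count in-mask voxel pairs separated by
``distance`` voxels along each of the 13 unique 3D directions; symmetric
pairing adds the transpose.  GLRLMs count maximal runs of equal gray level
along the same 13 directions, truncating runs at the mask boundary.

Features follow the standard radiomics definitions: 27 GLCM features and 16
GLRLM features, each computed per direction and then averaged over directions
with at least one valid pair/run.  Column names in cohort tables are
``glcm_<Feature>_<roi>`` / ``glrlm_<Feature>_<roi>`` with roi suffixes
``ipsi``/``contra``/``total`` — ``(27 + 16) x 3 = 129`` columns per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import (
    DoseGrid,
    EmptyRoiError,
    FeatureTable,
    ROI_SUFFIX,
    RoiMask,
    check_aligned,
)

log = logging.getLogger(__name__)

_EPS = np.finfo(float).eps

#: 13 unique 3D offsets (z, y, x): one of each +/- pair
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Dissimilarity", "JointEnergy",
    "JointEntropy", "Homogeneity1", "Homogeneity2", "Imc1", "Imc2", "Idm",
    "Idmn", "Id", "Idn", "InverseVariance", "MaximumProbability", "SumAverage",
    "SumEntropy", "SumSquares", "SumVariance",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


@dataclass(frozen=True)
class QuantizedGrid:
    """Integer gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray  # int32, (z, y, x)
    n_levels: int
    bin_edges: np.ndarray  # Gy, length n_levels + 1


@dataclass(frozen=True)
class GLCMatrix:
    """One co-occurrence matrix per direction, as joint probabilities."""

    matrices: tuple[np.ndarray, ...]  # Ng x Ng each, sum to 1 (or all-zero)
    directions: tuple[tuple[int, int, int], ...]
    valid: tuple[bool, ...]  # direction had at least one in-mask pair
    distance: int
    symmetric: bool


@dataclass(frozen=True)
class GLRLMatrix:
    """One run-length count matrix (Ng x Rmax) per direction."""

    matrices: tuple[np.ndarray, ...]
    directions: tuple[tuple[int, int, int], ...]
    n_voxels: int


def quantize(dose: DoseGrid, mask: RoiMask, n_levels: int = 64,
             bin_width: float | None = None) -> QuantizedGrid:
    """Equal-width quantisation of in-mask dose to gray levels 1..Ng.

    With ``bin_width`` set, the level count follows from the in-mask dose
    range instead.  A constant in-mask dose is the valid degenerate case
    Ng = 1.  The in-mask maximum maps to level Ng.
    """
    check_aligned(dose, mask)
    if mask.count == 0:
        raise EmptyRoiError("cannot quantise an empty ROI")
    d = dose.values[mask.values]
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:
        levels = np.zeros(dose.shape, dtype=np.int32)
        levels[mask.values] = 1
        return QuantizedGrid(levels, 1, np.array([lo, lo]))
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        ng = int(np.ceil((hi - lo) / bin_width))
    else:
        if n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        ng = int(n_levels)
    width = (hi - lo) / ng
    lv = np.minimum(np.floor((dose.values - lo) / width).astype(np.int64) + 1, ng)
    levels = np.zeros(dose.shape, dtype=np.int32)
    levels[mask.values] = lv[mask.values]
    return QuantizedGrid(levels, ng, lo + width * np.arange(ng + 1))


def _pair_slices(shape, offset):
    """Source/destination slice tuples for a voxel-pair offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_3d(q: QuantizedGrid, distance: int = 1,
            directions: tuple = DIRECTIONS_13, symmetric: bool = True) -> GLCMatrix:
    """Gray-level co-occurrence matrices for every direction."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = q.n_levels
    mats, valid = [], []
    for direction in directions:
        offset = tuple(int(distance) * c for c in direction)
        if any(abs(o) >= n for o, n in zip(offset, q.levels.shape)):
            mats.append(np.zeros((ng, ng)))
            valid.append(False)
            continue
        src, dst = _pair_slices(q.levels.shape, offset)
        a = q.levels[src].ravel()
        b = q.levels[dst].ravel()
        keep = (a > 0) & (b > 0)
        a, b = a[keep], b[keep]
        if a.size == 0:
            mats.append(np.zeros((ng, ng)))
            valid.append(False)
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        counts = counts.astype(float)
        if symmetric:
            counts = counts + counts.T
        mats.append(counts / counts.sum())
        valid.append(True)
    return GLCMatrix(tuple(mats), tuple(directions), tuple(valid), distance, symmetric)


@lru_cache(maxsize=64)
def _line_order(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Flat voxel ordering that walks each lattice line along ``direction``.

    Returns (order, line_id) where ``order`` indexes the flattened (z, y, x)
    array so that consecutive entries with equal ``line_id`` are consecutive
    voxels along the direction.
    """
    z, y, x = np.indices(shape).reshape(3, -1)
    dz, dy, dx = direction
    if dz != 0:
        t = z
        k1, k2 = y - dy * z, x - dx * z
    elif dy != 0:
        t = y
        k1, k2 = z, x - dx * y
    else:
        t = x
        k1, k2 = z, y
    order = np.lexsort((t, k2, k1))
    line_id = (k1.astype(np.int64) * (2 * max(shape) + 1) + k2)[order]
    return order, line_id


def glrlm_3d(q: QuantizedGrid, directions: tuple = DIRECTIONS_13) -> GLRLMatrix:
    """Gray-level run-length matrices; each in-mask voxel joins exactly one
    maximal run per direction, so ``sum_ij j * counts[i, j] = |mask|``."""
    ng = q.n_levels
    flat = q.levels.ravel()
    n_voxels = int((flat > 0).sum())
    mats = []
    for direction in directions:
        order, line_id = _line_order(q.levels.shape, direction)
        lv = flat[order]
        # run starts: first voxel of a line, or level change (level 0 breaks)
        new_run = np.empty(lv.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = (lv[1:] != lv[:-1]) | (line_id[1:] != line_id[:-1])
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, lv.size))
        run_levels = lv[starts]
        keep = run_levels > 0
        run_levels, lengths = run_levels[keep], lengths[keep]
        if lengths.size:
            rmax = int(lengths.max())
            counts = np.bincount(
                (run_levels.astype(np.int64) - 1) * rmax + (lengths - 1),
                minlength=ng * rmax,
            ).reshape(ng, rmax).astype(float)
        else:
            counts = np.zeros((ng, 1))
        mats.append(counts)
    return GLRLMatrix(tuple(mats), tuple(directions), n_voxels)


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng)  # |i-j| = 0..ng-1
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx, hy, hxy = ent(px), ent(py), ent(p)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    diff_avg = float((k_diff * p_diff).sum())
    feats = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": (
            float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sig_x * sig_y))
            if sig_x > 0 and sig_y > 0
            else 1.0  # degenerate single-level convention
        ),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float((p[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
        "SumVariance": float(((k_sum - (k_sum * p_sum).sum()) ** 2 * p_sum).sum()),
    }
    return feats


def glcm_features(glcm: GLCMatrix) -> dict[str, float]:
    """The 27 GLCM features, averaged over directions with valid pairs."""
    per_dir = [
        _glcm_features_single(m) for m, ok in zip(glcm.matrices, glcm.valid) if ok
    ]
    if not per_dir:
        raise EmptyRoiError("no direction produced a valid co-occurrence pair")
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_FEATURES
    }


def _glrlm_features_single(c: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, rmax = c.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, rmax + 1)[None, :]
    nr = c.sum()
    ri = c.sum(axis=1)  # runs per gray level
    rj = c.sum(axis=0)  # runs per length
    p = c / nr
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pz = p[p > 0]
    return {
        "ShortRunEmphasis": float((c / j**2).sum() / nr),
        "LongRunEmphasis": float((c * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rj**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "RunVariance": float(((j - mu_j) ** 2 * p).sum()),
        "RunEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelRunEmphasis": float((c / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((c * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((c / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((c * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((c * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((c * i**2 * j**2).sum() / nr),
    }


def glrlm_features(glrlm: GLRLMatrix) -> dict[str, float]:
    """The 16 GLRLM features, averaged over directions with at least one run."""
    per_dir = [
        _glrlm_features_single(m, glrlm.n_voxels)
        for m in glrlm.matrices
        if m.sum() > 0
    ]
    if not per_dir:
        raise EmptyRoiError("run-length matrix is empty in every direction")
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_FEATURES
    }


@dataclass(frozen=True)
class TextureConfig:
    """Extraction settings: quantisation, pair distance, pairing symmetry."""

    n_levels: int = 64
    bin_width: float | None = None
    distance: int = 1
    symmetric: bool = True


def dosiomics_columns() -> list[str]:
    """The stable 129-column order: roi-major, GLCM before GLRLM."""
    cols = []
    for role in ("ipsilateral", "contralateral", "total"):
        suffix = ROI_SUFFIX[role]
        cols += [f"glcm_{f}_{suffix}" for f in GLCM_FEATURES]
        cols += [f"glrlm_{f}_{suffix}" for f in GLRLM_FEATURES]
    return cols


def extract_patient_dosiomics(
    dose: DoseGrid, masks: dict[str, RoiMask], config: TextureConfig = TextureConfig()
) -> dict[str, float]:
    """All 129 texture features for one patient."""
    row: dict[str, float] = {}
    for role in ("ipsilateral", "contralateral", "total"):
        suffix = ROI_SUFFIX[role]
        q = quantize(dose, masks[role], n_levels=config.n_levels, bin_width=config.bin_width)
        log.debug(
            "roi=%s voxels=%d dose_range=[%.2f, %.2f] Gy levels=%d",
            role, masks[role].count, q.bin_edges[0], q.bin_edges[-1], q.n_levels,
        )
        gf = glcm_features(glcm_3d(q, distance=config.distance, symmetric=config.symmetric))
        rf = glrlm_features(glrlm_3d(q))
        for name, value in gf.items():
            row[f"glcm_{name}_{suffix}"] = value
        for name, value in rf.items():
            row[f"glrlm_{name}_{suffix}"] = value
    return row


def extract_dosiomics(
    cohort: list[tuple[str, DoseGrid, dict[str, RoiMask]]],
    config: TextureConfig = TextureConfig(),
    outcome: pd.Series | None = None,
) -> FeatureTable:
    """Texture feature table for a cohort of (patient_id, dose, role->mask).

    Any per-patient failure aborts the extraction with the patient id; rows
    are never silently imputed.
    """
    rows = {}
    for pid, dose, masks in cohort:
        try:
            rows[pid] = extract_patient_dosiomics(dose, masks, config)
        except Exception as exc:
            raise type(exc)(f"patient {pid}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index")[dosiomics_columns()]
    return FeatureTable(df, outcome=outcome)


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Z-score every column over the whole cohort (sample sd, ddof=1).

    The cohort-level transform matches the published procedure (normalise
    before any bootstrap resampling); stored parameters allow re-application.
    """
    if table.n_patients < 2:
        raise ValueError("z-scoring requires at least 2 patients")
    mean = table.features.mean(axis=0)
    sd = table.features.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"cannot z-score zero-variance column(s): {dead}")
    params = pd.DataFrame({"mean": mean, "sd": sd})
    feats = (table.features - mean) / sd
    return FeatureTable(feats, outcome=table.outcome, normalized=True, norm_params=params)


def apply_normalization(table: FeatureTable, params: pd.DataFrame) -> FeatureTable:
    """Apply stored z-score parameters to a (new) table."""
    feats = (table.features - params["mean"]) / params["sd"]
    return FeatureTable(feats, outcome=table.outcome, normalized=True, norm_params=params)
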