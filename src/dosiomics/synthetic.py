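"""Synthetic desk-scale cohorts: lung phantoms, VMAT-like dose, outcomes.

Each patient gets two disjoint ellipsoidal "lungs" (with small per-patient
jitter in position and size), a dose field made of a conformal
anisotropic-Gaussian high-dose lobe inside the ipsilateral lung (peak drawn
from the prescription distribution, 59.10 +/- 5.67 Gy), a low-dose bath, and
spatially correlated heterogeneity (Gaussian-filtered white noise whose
amplitude and correlation length vary per patient — the texture knobs).
Binary outcomes are drawn from a logistic model on features extracted by the
pipeline's own extractor, with the intercept calibrated so the expected event
rate matches the target (default 15/70 = 21.4%).

Everything is deterministic given the top-level seed; patient ``i`` uses
sub-streams ``default_rng([seed, i, stream])`` so patients are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from . import io as dio
from .core import DoseGrid, FeatureTable, RoiMask
from .dvh import dosimetric_factor_table, lung_set
from .ntcp import ntcp_factor_table
from .texture import TextureConfig, extract_dosiomics

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortConfig:
    """The stated world of the synthetic cohort."""

    n_patients: int = 70
    shape: tuple[int, int, int] = (32, 64, 64)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    p_left: float = 33.0 / 70.0  # tumor laterality distribution
    prescription_mean: float = 59.10  # Gy
    prescription_sd: float = 5.67
    bath_range: tuple[float, float] = (3.0, 7.0)  # Gy, per-patient uniform
    noise_amplitude_range: tuple[float, float] = (1.0, 6.0)  # Gy
    noise_corr_range: tuple[float, float] = (0.5, 2.5)  # voxels
    spot_count_range: tuple[int, int] = (0, 40)  # focal hot/cold spots
    spot_amplitude_range: tuple[float, float] = (2.0, 10.0)  # Gy (signed)
    spot_sigma_range: tuple[float, float] = (0.6, 1.2)  # voxels
    lung_semiaxes: tuple[float, float, float] = (11.0, 13.0, 8.0)  # voxels (z, y, x)
    center_jitter: float = 0.2  # voxels; small, so left/right stay near-mirror
    axis_jitter: float = 0.01  # relative
    outcome_features: dict[str, float] = field(
        default_factory=lambda: {
            "glcm_Contrast_ipsi": 1.0,
            "glrlm_LowGrayLevelRunEmphasis_total": 0.5,
        }
    )
    event_rate: float = 15.0 / 70.0
    outcome_on: str = "features"  # "features" | "noise_amplitude" (stress mode)
    seed: int = 0


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    return (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((xx - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def make_lung_masks(config: CohortConfig, patient_index: int) -> tuple[RoiMask, RoiMask]:
    """Two disjoint jittered ellipsoidal lungs; overlap triggers a logged redraw."""
    nz, ny, nx = config.shape
    # centred on (n-1)/2 so that a jitter-free left lung mirrors exactly
    # onto the right lung under the x-reflection  x -> nx-1-x
    base_centers = {
        "left": ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0 - nx * 0.17),
        "right": ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0 + nx * 0.17),
    }
    for attempt in range(100):
        rng = np.random.default_rng([config.seed, patient_index, 1, attempt])
        vols = {}
        for side in ("left", "right"):
            center = np.asarray(base_centers[side]) + rng.uniform(
                -config.center_jitter, config.center_jitter, size=3
            )
            axes = np.asarray(config.lung_semiaxes) * rng.uniform(
                1.0 - config.axis_jitter, 1.0 + config.axis_jitter, size=3
            )
            vols[side] = _ellipsoid(config.shape, center, axes)
        if not np.any(vols["left"] & vols["right"]):
            left = RoiMask(vols["left"], role="left", spacing=config.spacing)
            right = RoiMask(vols["right"], role="right", spacing=config.spacing)
            return left, right
        log.info("patient %d: lung overlap on attempt %d, redrawing", patient_index, attempt)
    raise RuntimeError(f"patient {patient_index}: grid too small for two disjoint lungs")


def make_dose(
    config: CohortConfig,
    left: RoiMask,
    right: RoiMask,
    tumor_side: str,
    patient_index: int,
) -> tuple[DoseGrid, dict[str, float]]:
    """VMAT-like dose: ipsilateral Gaussian lobe + bath + correlated noise.

    Returns the grid and the latent per-patient parameters (prescription,
    bath, noise amplitude, correlation length) for diagnostics/stress mode.
    """
    rng = np.random.default_rng([config.seed, patient_index, 2])
    ipsi = left if tumor_side == "left" else right
    prescription = float(rng.normal(config.prescription_mean, config.prescription_sd))
    prescription = max(prescription, 20.0)
    bath = float(rng.uniform(*config.bath_range))
    amplitude = float(rng.uniform(*config.noise_amplitude_range))
    corr = float(rng.uniform(*config.noise_corr_range))

    centroid = np.mean(np.argwhere(ipsi.values), axis=0)
    center = centroid + rng.uniform(-2.0, 2.0, size=3)
    sigma = np.asarray(config.lung_semiaxes) * rng.uniform(0.40, 0.65, size=3)
    zz, yy, xx = np.indices(config.shape, dtype=float)
    r2 = (
        ((zz - center[0]) / sigma[0]) ** 2
        + ((yy - center[1]) / sigma[1]) ** 2
        + ((xx - center[2]) / sigma[2]) ** 2
    )
    dose = bath + (prescription - bath) * np.exp(-0.5 * r2)

    if amplitude > 0:
        white = rng.standard_normal(config.shape)
        smooth = gaussian_filter(white, sigma=corr)
        smooth /= smooth.std()
        dose = dose + amplitude * smooth

    # focal hot/cold spots: a non-Gaussian texture axis.  A purely Gaussian
    # random field would make every local-difference statistic a monotone
    # function of one scale parameter; focal modulation varies the tail
    # weight so quadratic and linear difference features genuinely differ.
    n_spots = int(rng.integers(config.spot_count_range[0], config.spot_count_range[1] + 1))
    if n_spots > 0:
        spikes = np.zeros(config.shape)
        lung_voxels = np.argwhere(left.values | right.values)
        pos = tuple(lung_voxels[rng.integers(0, len(lung_voxels), n_spots)].T)
        amps = rng.uniform(*config.spot_amplitude_range, n_spots)
        amps *= rng.choice([-1.0, 1.0], n_spots)
        np.add.at(spikes, pos, amps)
        spot_sigma = float(rng.uniform(*config.spot_sigma_range))
        # rescale so each spot's peak is ~ its drawn amplitude
        dose = dose + gaussian_filter(spikes, spot_sigma) * (2 * np.pi) ** 1.5 * spot_sigma**3
    dose = np.clip(dose, 0.0, None)
    latent = {
        "prescription": prescription,
        "bath": bath,
        "noise_amplitude": amplitude,
        "noise_corr": corr,
        "n_spots": float(n_spots),
    }
    return DoseGrid(dose, spacing=config.spacing), latent


def sample_outcomes(
    features: FeatureTable,
    outcome_model: dict[str, float],
    event_rate: float,
    seed: int,
) -> pd.Series:
    """Bernoulli outcomes from a logistic model on z-scored named features.

    The intercept is calibrated so the cohort-average event probability
    equals ``event_rate``.  An all-0/all-1 draw is redrawn with an advanced
    sub-seed (logged).
    """
    missing = [f for f in outcome_model if f not in features.columns]
    if missing:
        raise KeyError(f"outcome model references unknown features: {missing}")
    X = features.features[list(outcome_model)].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    lp = (X - mu) / sd @ np.asarray(list(outcome_model.values()), dtype=float)

    def mean_prob(c: float) -> float:
        return float(expit(c + lp).mean()) - event_rate

    intercept = brentq(mean_prob, -30.0, 30.0)
    for attempt in range(100):
        rng = np.random.default_rng([seed, 3, attempt])
        y = (rng.uniform(size=lp.size) < expit(intercept + lp)).astype(int)
        if 0 < y.sum() < y.size:
            return pd.Series(y, index=features.features.index, name="outcome")
        log.info("degenerate outcome draw on attempt %d, redrawing", attempt)
    raise RuntimeError("could not draw a two-class outcome vector")


@dataclass
class Patient:
    pid: str
    tumor_side: str
    dose: DoseGrid
    left: RoiMask
    right: RoiMask
    masks: dict[str, RoiMask]  # ipsilateral / contralateral / total
    latent: dict[str, float]


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[Patient]
    features: FeatureTable  # raw (un-normalised), outcome attached

    @property
    def outcome(self) -> pd.Series:
        return self.features.outcome


def generate_cohort(
    config: CohortConfig,
    feature_sets: tuple[str, ...] = ("dosiomics",),
    texture_config: TextureConfig = TextureConfig(),
) -> Cohort:
    """End-to-end deterministic cohort: masks, dose, features, outcomes."""
    patients: list[Patient] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i, 0])
        side = "left" if rng.uniform() < config.p_left else "right"
        left, right = make_lung_masks(config, i)
        dose, latent = make_dose(config, left, right, side, i)
        ipsi, contra, total = lung_set(left, right, side)
        patients.append(
            Patient(
                pid=f"P{i:03d}",
                tumor_side=side,
                dose=dose,
                left=left,
                right=right,
                masks={"ipsilateral": ipsi, "contralateral": contra, "total": total},
                latent=latent,
            )
        )
    triples = [(p.pid, p.dose, p.masks) for p in patients]
    tables = []
    if "dosiomics" in feature_sets:
        tables.append(extract_dosiomics(triples, texture_config))
    if "dosimetric" in feature_sets:
        tables.append(dosimetric_factor_table(triples))
    if "ntcp" in feature_sets:
        tables.append(ntcp_factor_table(triples))
    if not tables:
        raise ValueError("feature_sets must name at least one feature set")
    features = tables[0]
    for extra in tables[1:]:
        features = FeatureTable(
            features.features.join(extra.features), outcome=features.outcome
        )

    if config.outcome_on == "features":
        outcome = sample_outcomes(
            features, config.outcome_features, config.event_rate, config.seed
        )
    elif config.outcome_on == "noise_amplitude":  # latent-field stress mode
        latent = FeatureTable(
            pd.DataFrame(
                {"noise_amplitude": [p.latent["noise_amplitude"] for p in patients]},
                index=features.features.index,
            )
        )
        beta = sum(abs(v) for v in config.outcome_features.values()) or 1.0
        outcome = sample_outcomes(
            latent, {"noise_amplitude": beta}, config.event_rate, config.seed
        )
    else:
        raise ValueError(f"unknown outcome_on mode {config.outcome_on!r}")
    features.outcome = outcome.reindex(features.features.index).astype(int)
    return Cohort(config=config, patients=patients, features=features)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write NIfTI dose + lung masks, a labels CSV and the feature CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = []
    for p in cohort.patients:
        dio.write_dose_nifti(p.dose, outdir / f"{p.pid}_dose.nii.gz")
        dio.write_mask(p.left, outdir / f"{p.pid}_lung_left.nii.gz")
        dio.write_mask(p.right, outdir / f"{p.pid}_lung_right.nii.gz")
        labels.append(
            {
                "patient_id": p.pid,
                "tumor_side": p.tumor_side,
                "outcome": int(cohort.outcome.loc[p.pid]),
            }
        )
    pd.DataFrame(labels).set_index("patient_id").to_csv(outdir / "labels.csv")
    cohort.features.to_csv(outdir / "features.csv")


def read_cohort_inputs(indir) -> list[tuple[str, DoseGrid, dict[str, RoiMask], str]]:
    """Load (pid, dose, masks, side) tuples from a written cohort directory."""
    indir = Path(indir)
    labels = pd.read_csv(indir / "labels.csv", index_col="patient_id")
    out = []
    for pid, row in labels.iterrows():
        dose = dio.read_dose_nifti(indir / f"{pid}_dose.nii.gz")
        left = dio.read_mask(indir / f"{pid}_lung_left.nii.gz", role="left", grid=dose)
        right = dio.read_mask(indir / f"{pid}_lung_right.nii.gz", role="right", grid=dose)
        ipsi, contra, total = lung_set(left, right, row["tumor_side"])
        out.append(
            (pid, dose, {"ipsilateral": ipsi, "contralateral": contra, "total": total},
             row["tumor_side"])
        )
    return out
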