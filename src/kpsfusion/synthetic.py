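"""Synthetic glioblastoma cohort generator.

Stands in for the single-center cohort the prediction pipeline was designed
for (which is not publicly available): it draws a clinical table whose
marginal frequencies match the published baseline characteristics of a
150-patient IDH wild-type glioblastoma population, builds parametric pre- and
postoperative label volumes (ellipsoidal lesion core + edema shell inside a
brain ellipsoid, resected according to the recorded extent of resection), and
plants a logistic outcome model linking clinical covariates and tumor
morphology to the binary endpoint (6-month postoperative KPS < 70).

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import schema
from .volumes import BRAIN, CORE, EDEMA, LabelVolume

# Marginal targets: fraction of patients positive for each binary parameter,
# from the published overall-cohort column (counts / 150).
DEFAULT_BINARY_MARGINALS: dict[str, float] = {
    "sex_female": 65 / 150,
    "dominant_hand_right": 147 / 150,
    "epilepsy": 40 / 150,
    "aphasia": 42 / 150,
    "paralysis": 67 / 150,
    "other_neuro": 102 / 150,
    "surgery_biopsy": 27 / 150,
    "awake_surgery": 54 / 150,
    "five_ala": 78 / 150,
    "pdt": 7 / 150,
    "carmustine": 36 / 150,
    "mep_sep": 76 / 150,
    "mgmt_methylation": 51 / 150,
    "tertp": 49 / 150,
    "mgmt_ihc": 54 / 150,
    "tmz": 142 / 150,
    "bevacizumab": 65 / 150,
    "ependymal_invasion": 107 / 150,
    "midline_shift": 63 / 150,
    "corpus_callosum_invasion": 41 / 150,
    "necrosis_cyst": 138 / 150,
}

DEFAULT_LATERALITY_PROBS = (75 / 150, 63 / 150, 12 / 150)  # right, left, bilateral
DEFAULT_EXTENT_PROBS = (30 / 150, 21 / 150, 43 / 150, 56 / 150)

# Preoperative KPS distribution on the 10-point grid (20..100): median 80,
# ~79% of patients at KPS >= 70.
PREOP_KPS_VALUES = (20, 30, 40, 50, 60, 70, 80, 90, 100)
PREOP_KPS_PROBS = (0.02, 0.03, 0.05, 0.05, 0.06, 0.14, 0.26, 0.24, 0.15)

MORPHOLOGY_COVARIATES = ("pre_core_volume", "post_core_volume", "edema_volume")


@dataclass
class CohortConfig:
    """Stated world of the generator; defaults follow the published cohort."""

    grid_shape: tuple[int, int, int] = (32, 64, 64)  # slices, H, W
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # mm; 3-mm slices
    binary_marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_MARGINALS))
    laterality_probs: tuple[float, float, float] = DEFAULT_LATERALITY_PROBS
    extent_probs: tuple[float, float, float, float] = DEFAULT_EXTENT_PROBS
    age_mean: float = 64.0
    age_sd: float = 13.0
    age_range: tuple[int, int] = (21, 92)
    mib1_median: float = 22.5
    mib1_log_sd: float = 0.55
    mib1_range: tuple[float, float] = (0.0, 90.0)
    untreated_fraction: float = 0.07  # no radiotherapy (dose 0, 0 fractions)
    elderly_age: int = 70  # hypofractionated 40.05 Gy / 15 Fr at this age and above
    date_start: date = date(2001, 12, 1)
    date_end: date = date(2022, 12, 31)
    core_radius_range: tuple[float, float] = (3.0, 10.0)  # voxels, in-plane
    edema_margin_range: tuple[float, float] = (2.0, 6.0)  # voxels
    boundary_jitter: float = 0.0  # relative radius jitter of the core surface
    missingness_rate: float = 0.0


@dataclass
class TumorGeometry:
    """Parametric tumor: core ellipsoid + edema shell inside a brain ellipsoid."""

    center: np.ndarray  # (3,) voxel coords (slice, row, col)
    core_radii: np.ndarray  # (3,) voxels
    edema_margin: float  # shell thickness added to core radii, voxels
    brain_center: np.ndarray
    brain_radii: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.core_radii = np.asarray(self.core_radii, dtype=float)
        self.brain_center = np.asarray(self.brain_center, dtype=float)
        self.brain_radii = np.asarray(self.brain_radii, dtype=float)
        if (self.core_radii <= 0).any():
            raise ValueError("core radii must be positive")
        if self.edema_margin < 0:
            raise ValueError("edema margin must be non-negative")
        if (self.brain_radii <= 0).any():
            raise ValueError("brain radii must be positive")


@dataclass
class OutcomeModel:
    """Planted logistic model for P(6-month postoperative KPS < 70).

    Coefficients act on per-cohort z-scored covariates, so with all
    coefficients zero the label prevalence is ``logistic(intercept)``.
    ``clinical_coefs`` keys are clinical parameter names (``laterality`` and
    ``extent_of_resection`` enter as ordinal codes); ``morphology_coefs``
    keys are {pre_core_volume, post_core_volume, edema_volume} (mm^3).
    """

    intercept: float = 0.0
    clinical_coefs: dict[str, float] = field(default_factory=dict)
    morphology_coefs: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 0.0

    def validate(self) -> None:
        known = set(schema.CLINICAL_PARAMS)
        for name in self.clinical_coefs:
            if name not in known:
                raise ValueError(f"unknown clinical parameter in outcome model: {name!r}")
        for name in self.morphology_coefs:
            if name not in MORPHOLOGY_COVARIATES:
                raise ValueError(f"unknown morphology covariate: {name!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _ellipsoid_mask(grid_shape, center, radii) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    q = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return q <= 1.0


def simulate_tumor_volume(geometry: TumorGeometry, grid_shape,
                          seed: int | np.random.Generator = 0,
                          spacing=(3.0, 1.0, 1.0),
                          boundary_jitter: float = 0.0,
                          patient_id: str = "", timepoint: str = "pre") -> LabelVolume:
    """Rasterise a tumor geometry into a label volume.

    Labels: 0 background, 1 brain, 2 edema shell, 3 lesion core. With
    ``boundary_jitter > 0`` the core surface radius is perturbed
    multiplicatively (log-normal per-voxel smooth field approximated by a
    radial jitter drawn once per volume).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid_shape = tuple(int(s) for s in grid_shape)
    hi = np.asarray(grid_shape, dtype=float)
    outer = geometry.core_radii + geometry.edema_margin
    if ((geometry.center - outer) < 0).any() or ((geometry.center + outer) > hi - 1).any():
        raise ValueError("tumor geometry does not fit inside the grid")

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[_ellipsoid_mask(grid_shape, geometry.brain_center, geometry.brain_radii)] = BRAIN
    core_radii = geometry.core_radii
    if boundary_jitter > 0:
        core_radii = core_radii * np.exp(rng.normal(0.0, boundary_jitter, size=3))
    labels[_ellipsoid_mask(grid_shape, geometry.center, core_radii + geometry.edema_margin)] = EDEMA
    labels[_ellipsoid_mask(grid_shape, geometry.center, core_radii)] = CORE
    return LabelVolume(labels=labels, spacing=tuple(spacing),
                       patient_id=patient_id, timepoint=timepoint)


# Resected fraction of the core, sampled uniformly within the category range.
EXTENT_FRACTION_RANGES = {
    "1-49%": (0.01, 0.49),
    "50-89%": (0.50, 0.89),
    "90-99%": (0.90, 0.99),
    "100%": (1.0, 1.0),
}


def apply_resection(pre: LabelVolume, extent_of_resection: str,
                    seed: int | np.random.Generator = 0) -> LabelVolume:
    """Relabel a resected fraction of core voxels to brain parenchyma.

    The fraction is drawn uniformly from the extent category's range; the
    resected voxels are a random subset of the core (a cavity model is not
    attempted — downstream features only use label counts and coarse shape).
    """
    if extent_of_resection not in EXTENT_FRACTION_RANGES:
        raise ValueError(f"unknown extent category: {extent_of_resection!r}")
    core_idx = np.flatnonzero(pre.labels == CORE)
    if core_idx.size == 0:
        raise ValueError("preoperative volume has no lesion-core voxels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = EXTENT_FRACTION_RANGES[extent_of_resection]
    frac = 1.0 if lo == hi == 1.0 else rng.uniform(lo, hi)
    n_resect = int(np.round(frac * core_idx.size))
    chosen = rng.choice(core_idx, size=n_resect, replace=False)
    labels = pre.labels.copy()
    labels.flat[chosen] = BRAIN
    return LabelVolume(labels=labels, spacing=pre.spacing,
                       patient_id=pre.patient_id, timepoint="post")


def _sample_clinical(n: int, cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the 28 clinical parameters (no outcome yet)."""
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    span = (cfg.date_end - cfg.date_start).days
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    df["operation_date"] = [cfg.date_start + timedelta(days=int(d)) for d in offsets]

    for name, p in cfg.binary_marginals.items():
        df[name] = (rng.random(n) < p).astype(int)

    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, n)),
                  *cfg.age_range).astype(int)
    df["age"] = age
    df["preop_kps"] = rng.choice(PREOP_KPS_VALUES, size=n, p=PREOP_KPS_PROBS)
    mib1 = np.exp(np.log(cfg.mib1_median) + rng.normal(0.0, cfg.mib1_log_sd, n))
    df["mib1_index"] = np.clip(np.round(mib1, 1), *cfg.mib1_range)

    untreated = rng.random(n) < cfg.untreated_fraction
    elderly = age >= cfg.elderly_age
    df["radiation_dose"] = np.where(untreated, 0.0, np.where(elderly, 40.05, 60.0))
    df["radiation_fractions"] = np.where(untreated, 0, np.where(elderly, 15, 30))

    df["laterality"] = rng.choice(schema.LATERALITY_LEVELS, size=n,
                                  p=cfg.laterality_probs)
    df["extent_of_resection"] = rng.choice(schema.EXTENT_LEVELS, size=n,
                                           p=cfg.extent_probs)
    # biopsy-only surgery removes (almost) no tumor: force the lowest category
    df.loc[df["surgery_biopsy"] == 1, "extent_of_resection"] = schema.EXTENT_LEVELS[0]
    return df


def _sample_geometry(cfg: CohortConfig, rng: np.random.Generator) -> TumorGeometry:
    grid = np.asarray(cfg.grid_shape, dtype=float)
    brain_center = (grid - 1) / 2.0
    brain_radii = 0.45 * grid * rng.uniform(0.95, 1.05, size=3)
    # in-plane radii from the config range; through-plane scaled by anisotropy
    r_inplane = rng.uniform(*cfg.core_radius_range, size=2)
    r_slice = max(1.5, rng.uniform(*cfg.core_radius_range) * cfg.spacing[1] / cfg.spacing[0])
    core_radii = np.array([r_slice, r_inplane[0], r_inplane[1]])
    edema_margin = float(rng.uniform(*cfg.edema_margin_range))
    # clamp so core + edema always fits the grid with a 2-voxel border
    max_outer = (grid - 5.0) / 2.0
    core_radii = np.minimum(core_radii, np.maximum(max_outer - edema_margin, 1.0))
    outer = core_radii + edema_margin
    # place the centre so the outer shell stays inside the grid
    lo = outer + 1.0
    hi = grid - 2.0 - outer
    center = np.array([rng.uniform(l, h) if h > l else brain_center[i]
                       for i, (l, h) in enumerate(zip(lo, hi))])
    # pull toward the brain centre so the tumor sits inside parenchyma
    center = 0.6 * center + 0.4 * brain_center
    return TumorGeometry(center=center, core_radii=core_radii,
                         edema_margin=edema_margin,
                         brain_center=brain_center, brain_radii=brain_radii)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _covariate_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "laterality":
        return df[name].map({lv: i for i, lv in enumerate(schema.LATERALITY_LEVELS)}
                            ).to_numpy(dtype=float)
    if name == "extent_of_resection":
        return df[name].map({lv: i for i, lv in enumerate(schema.EXTENT_LEVELS)}
                            ).to_numpy(dtype=float)
    return df[name].to_numpy(dtype=float)


def simulate_cohort(n_patients: int, outcome_model: OutcomeModel | None = None,
                    config: CohortConfig | None = None, seed: int = 0,
                    make_volumes: bool = True):
    """Simulate a full cohort.

    Returns ``(clinical, studies)``: a DataFrame with one row per patient
    (28 predictors + operation date + 6-month postoperative KPS endpoint) and
    a list of ``(pre, post)`` :class:`LabelVolume` pairs (empty when
    ``make_volumes`` is False; morphology covariates are then ellipsoid
    volumes computed analytically from the geometry).
    """
    if n_patients < 10:
        raise ValueError("n_patients must be >= 10")
    cfg = config or CohortConfig()
    model = outcome_model or OutcomeModel()
    model.validate()
    rng = np.random.default_rng(seed)

    df = _sample_clinical(n_patients, cfg, rng)

    voxel_mm3 = float(np.prod(cfg.spacing))
    studies: list[tuple[LabelVolume, LabelVolume]] = []
    pre_core = np.zeros(n_patients)
    post_core = np.zeros(n_patients)
    edema_vol = np.zeros(n_patients)
    for i in range(n_patients):
        geom = _sample_geometry(cfg, rng)
        if make_volumes:
            pid = df.at[i, "patient_id"]
            pre = simulate_tumor_volume(geom, cfg.grid_shape, rng, cfg.spacing,
                                        cfg.boundary_jitter, pid, "pre")
            post = apply_resection(pre, df.at[i, "extent_of_resection"], rng)
            studies.append((pre, post))
            pre_core[i] = (pre.labels == CORE).sum() * voxel_mm3
            post_core[i] = (post.labels == CORE).sum() * voxel_mm3
            edema_vol[i] = (pre.labels == EDEMA).sum() * voxel_mm3
        else:
            core = 4.0 / 3.0 * np.pi * np.prod(geom.core_radii) * voxel_mm3
            outer = 4.0 / 3.0 * np.pi * np.prod(geom.core_radii + geom.edema_margin) * voxel_mm3
            lo_f, hi_f = EXTENT_FRACTION_RANGES[df.at[i, "extent_of_resection"]]
            frac = 1.0 if lo_f == hi_f == 1.0 else rng.uniform(lo_f, hi_f)
            pre_core[i] = core
            post_core[i] = core * (1.0 - frac)
            edema_vol[i] = outer - core

    morph = {"pre_core_volume": pre_core, "post_core_volume": post_core,
             "edema_volume": edema_vol}

    score = np.full(n_patients, model.intercept, dtype=float)
    for name, coef in model.clinical_coefs.items():
        score += coef * _zscore(_covariate_column(df, name))
    for name, coef in model.morphology_coefs.items():
        score += coef * _zscore(morph[name])
    if model.noise_scale > 0:
        score += rng.normal(0.0, model.noise_scale, n_patients)
    p = 1.0 / (1.0 + np.exp(-score))
    label = rng.random(n_patients) < p

    # endpoint on the 10-point grid, consistent with the binary label
    low = rng.choice([0, 10, 20, 30, 40, 50, 60], size=n_patients,
                     p=[0.06, 0.08, 0.12, 0.20, 0.22, 0.18, 0.14])
    high = rng.choice([70, 80, 90, 100], size=n_patients, p=[0.35, 0.33, 0.22, 0.10])
    df[schema.ENDPOINT] = np.where(label, low, high)

    for key, vals in morph.items():
        df[key] = vals  # generative covariates kept for diagnostics; not predictors

    if cfg.missingness_rate > 0:
        mask_cols = list(schema.CLINICAL_PARAMS)
        for col in mask_cols:
            miss = rng.random(n_patients) < cfg.missingness_rate
            if miss.any():
                df[col] = df[col].astype(object)
                df.loc[miss, col] = np.nan

    return df, studies


def write_clinical_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["operation_date"] = pd.to_datetime(out["operation_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["operation_date"] = pd.to_datetime(df["operation_date"]).dt.date
    return df
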