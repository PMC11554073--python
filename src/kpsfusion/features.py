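"""Numeric encoding of clinical records and assembly of the design matrices.

Three matrices feed the classifiers: clinical-only (the 28 parameters,
numerically encoded to 30 columns), MRI-only (the VAE latent features), and
multimodal (their horizontal concatenation). The positive class is
6-month postoperative KPS < 70. Continuous covariates are z-scored with
training-split statistics only; missing values are imputed from the training
split (median for continuous, mode otherwise) and an imputation report is
kept alongside the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .vae import MriFeatureVector

MODES = ("clinical", "mri", "multimodal")


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (patients, features)
    feature_names: list[str]
    feature_groups: list[str]  # one group per column; partitions the columns
    label: np.ndarray  # 1 = postoperative KPS < 70
    patient_ids: list[str]
    split_tag: str = ""
    imputation_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    def subset(self, ids) -> "FeatureMatrix":
        idx = [self.patient_ids.index(i) for i in ids]
        return FeatureMatrix(self.values[idx], self.feature_names,
                             self.feature_groups, self.label[idx],
                             [self.patient_ids[i] for i in idx],
                             self.split_tag, self.imputation_report)


@dataclass
class ScalingStats:
    mean: dict[str, float]
    std: dict[str, float]
    fill: dict[str, object]  # imputation values (train median / mode)


def _impute(df: pd.DataFrame, train_mask: np.ndarray):
    """Train-split imputation; returns (filled df, fill values, report)."""
    out = df.copy()
    fill: dict[str, object] = {}
    report: dict[str, int] = {}
    for col in schema.CLINICAL_PARAMS:
        s = out[col]
        missing = s.isna()
        train_vals = s[train_mask & ~missing]
        if train_vals.empty:
            raise ValueError(f"column {col!r} has no observed training values")
        if col in schema.CONTINUOUS_PARAMS:
            fv = float(pd.to_numeric(train_vals).median())
        else:
            fv = train_vals.mode().iloc[0]
        fill[col] = fv
        if missing.any():
            report[col] = int(missing.sum())
            out[col] = s.where(~missing, fv)
    return out, fill, report


def encode_clinical(df: pd.DataFrame, train_mask: np.ndarray | None = None,
                    stats: ScalingStats | None = None):
    """Encode the 28 clinical parameters into a numeric block.

    Binaries stay 0/1; laterality becomes a 3-column one-hot (one logical
    parameter); extent of resection becomes the ordinal 0..3; the five
    continuous parameters are z-scored. ``train_mask`` marks the rows whose
    statistics are used for scaling and imputation (all rows when omitted);
    pass the returned :class:`ScalingStats` back in to encode new rows with
    frozen training statistics.

    Returns ``(FeatureMatrix, ScalingStats)``.
    """
    df = df.reset_index(drop=True)
    n = len(df)
    train_mask = np.ones(n, bool) if train_mask is None else np.asarray(train_mask, bool)

    if stats is None:
        filled, fill, report = _impute(df, train_mask)
    else:
        filled, _, report = _impute_with(df, stats.fill)
        fill = stats.fill

    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[str] = []
    mean: dict[str, float] = {} if stats is None else stats.mean
    std: dict[str, float] = {} if stats is None else stats.std

    for param in schema.CLINICAL_PARAMS:
        if param == "laterality":
            vals = filled[param].astype(str)
            unknown = set(vals) - set(schema.LATERALITY_LEVELS)
            if unknown:
                raise ValueError(f"unknown laterality level(s): {sorted(unknown)}")
            for lv in schema.LATERALITY_LEVELS:
                cols.append((vals == lv).to_numpy(float))
                names.append(f"laterality_{lv}")
                groups.append("laterality")
        elif param == "extent_of_resection":
            mapping = {lv: i for i, lv in enumerate(schema.EXTENT_LEVELS)}
            vals = filled[param].astype(str)
            unknown = set(vals) - set(mapping)
            if unknown:
                raise ValueError(f"unknown extent level(s): {sorted(unknown)}")
            cols.append(vals.map(mapping).to_numpy(float))
            names.append(param)
            groups.append(param)
        elif param in schema.CONTINUOUS_PARAMS:
            x = pd.to_numeric(filled[param]).to_numpy(float)
            if stats is None:
                mean[param] = float(x[train_mask].mean())
                sd = float(x[train_mask].std(ddof=0))
                std[param] = sd if sd > 0 else 1.0
            cols.append((x - mean[param]) / std[param])
            names.append(param)
            groups.append(param)
        else:  # binary
            x = pd.to_numeric(filled[param]).to_numpy(float)
            if not np.isin(x, (0.0, 1.0)).all():
                raise ValueError(f"binary parameter {param!r} has non-0/1 values")
            cols.append(x)
            names.append(param)
            groups.append(param)

    label = (pd.to_numeric(df[schema.ENDPOINT]).to_numpy() < 70).astype(int)
    fm = FeatureMatrix(values=np.column_stack(cols), feature_names=names,
                       feature_groups=groups, label=label,
                       patient_ids=[str(p) for p in df["patient_id"]],
                       imputation_report=report)
    return fm, ScalingStats(mean=mean, std=std, fill=fill)


def _impute_with(df: pd.DataFrame, fill: dict[str, object]):
    out = df.copy()
    report: dict[str, int] = {}
    for col in schema.CLINICAL_PARAMS:
        missing = out[col].isna()
        if missing.any():
            report[col] = int(missing.sum())
            out[col] = out[col].where(~missing, fill[col])
    return out, fill, report


def build_matrix(clinical: pd.DataFrame, mode: str,
                 mri_features: dict[str, MriFeatureVector] | None = None,
                 train_mask: np.ndarray | None = None,
                 stats: ScalingStats | None = None,
                 scale_mri: bool = True) -> FeatureMatrix:
    """Assemble the design matrix for one model variant.

    Rows are sorted by patient_id, identically across modes. For ``mri`` and
    ``multimodal`` modes, patients without extracted MRI features are dropped
    with a warning naming them. MRI latent columns are z-scored with
    training-split statistics (``scale_mri=False`` uses the raw latents).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    clinical = clinical.sort_values("patient_id").reset_index(drop=True)
    if train_mask is not None:
        train_mask = np.asarray(train_mask, bool)
        if len(train_mask) != len(clinical):
            raise ValueError("train_mask length must match the (sorted) table")

    if mode in ("mri", "multimodal"):
        if mri_features is None:
            raise ValueError(f"mode {mode!r} requires extracted MRI features")
        have = clinical["patient_id"].astype(str).isin(mri_features).to_numpy()
        if not have.all():
            dropped = clinical.loc[~have, "patient_id"].tolist()
            warnings.warn(f"dropping {len(dropped)} patient(s) without MRI features: "
                          f"{dropped}")
            clinical = clinical[have].reset_index(drop=True)
            if train_mask is not None:
                train_mask = train_mask[have]

    clin_fm, _ = encode_clinical(clinical, train_mask, stats)

    if mode == "clinical":
        return clin_fm

    first = mri_features[clin_fm.patient_ids[0]]
    mri_vals = np.stack([mri_features[p].values for p in clin_fm.patient_ids])
    if scale_mri:
        tm = np.ones(len(clin_fm.patient_ids), bool) if train_mask is None else train_mask
        mu = mri_vals[tm].mean(axis=0)
        sd = mri_vals[tm].std(axis=0)
        sd[sd == 0] = 1.0
        mri_vals = (mri_vals - mu) / sd
    mri_fm = FeatureMatrix(values=mri_vals, feature_names=list(first.names),
                           feature_groups=list(first.groups), label=clin_fm.label,
                           patient_ids=clin_fm.patient_ids,
                           imputation_report=clin_fm.imputation_report)
    if mode == "mri":
        return mri_fm
    return FeatureMatrix(
        values=np.hstack([clin_fm.values, mri_fm.values]),
        feature_names=clin_fm.feature_names + mri_fm.feature_names,
        feature_groups=clin_fm.feature_groups + mri_fm.feature_groups,
        label=clin_fm.label, patient_ids=clin_fm.patient_ids,
        imputation_report=clin_fm.imputation_report)
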