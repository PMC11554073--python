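"""End-to-end study pipeline: simulate → extract → encode → train → evaluate.

`run_study` performs the whole analysis in memory and is what the analysis
scripts, tests and acceptance script call; `run_pipeline` wraps it with config
parsing, file outputs and a run manifest for the command line.

Stages: (1) synthesise a cohort (clinical table + pre/post label volumes),
(2) select one 24-slice window per patient (on the preoperative tumor) and
split channels, (3) pretrain the lesion and mask VAEs on an independent
synthetic corpus and extract 48-dim latents, (4) encode the clinical table
and assemble clinical / MRI / multimodal matrices with a 2:1 temporal split,
(5) repeated stratified CV of the neural net on the training split (plus
optional grid-searched tree baselines), held-out test evaluation, (6) grouped
permutation importance on the test split, and (7) the univariate baseline
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (CvReport, compute_metrics, mean_roc_curve,
                         paired_t_test, repeated_cv, temporal_split)
from .features import FeatureMatrix, build_matrix
from .importance import (feature_groups_from_columns,
                         grouped_permutation_importance)
from .models import (DEFAULT_GRIDS, GridSearchSpec, NnConfig, fit_baseline,
                     predict_proba, train_nn)
from .synthetic import CohortConfig, OutcomeModel, simulate_cohort, write_clinical_csv
from .table1 import build_table1, table1_markdown
from .vae import Vae, VaeConfig, assemble_mri_features, pretrain, save_checkpoint
from .volumes import make_patient_stacks

# Stated world for the default synthetic study: the outcome signal is split
# half/half between clinical covariates (age up, preoperative KPS down) and
# tumor morphology (residual core and edema volume up) — the planted variance
# of each block is ~2.0 on z-scored covariates — with prevalence ~0.4 as in
# the real cohort.
DEFAULT_OUTCOME_MODEL = OutcomeModel(
    intercept=-0.4,
    clinical_coefs={"age": 1.0, "preop_kps": -1.0},
    morphology_coefs={"post_core_volume": 1.2, "edema_volume": 0.7},
    noise_scale=0.5,
)


@dataclass
class StudyConfig:
    n_patients: int = 150
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcome: OutcomeModel = field(default_factory=lambda: dataclasses.replace(
        DEFAULT_OUTCOME_MODEL))
    # the VAEs are pretrained on an independent synthetic corpus (the stand-in
    # for external public pretraining data), never on the study cohort
    n_pretrain_patients: int = 250
    vae_hidden: tuple[int, ...] = (128,)
    vae_epochs: int = 8
    vae_latent: int = 48
    nn: NnConfig = field(default_factory=lambda: NnConfig(
        dropout=0.5, learning_rate=3e-3))
    folds: int = 5
    repeats: int = 10
    modes: tuple[str, ...] = ("clinical", "mri", "multimodal")
    baselines: tuple[str, ...] = ()  # e.g. ("random_forest", "gradient_boosting")
    n_permutations: int = 30
    augment_scalars: bool = False


@dataclass
class StudyResult:
    clinical: pd.DataFrame
    train_ids: list[str]
    test_ids: list[str]
    matrices: dict[str, FeatureMatrix]
    cv_reports: dict[str, CvReport]
    test_metrics: dict[str, dict]
    comparisons: dict[str, dict]
    importance: pd.DataFrame | None
    table1: pd.DataFrame
    vae1: Vae | None = None
    vae2: Vae | None = None
    loss_histories: dict[str, list[float]] = field(default_factory=dict)


def pretraining_corpus(cfg: StudyConfig) -> list:
    """Independent synthetic slice stacks for VAE pretraining.

    Emulates pretraining on an external public dataset: the corpus is drawn
    with its own seed and shares no patients with the study cohort.
    """
    _, studies = simulate_cohort(cfg.n_pretrain_patients, cfg.outcome,
                                 cfg.cohort, seed=cfg.seed + 100_000)
    return [s for pre, post in studies for s in make_patient_stacks(pre, post)]


def extract_cohort_features(studies, cfg: StudyConfig, corpus=None):
    """Slice-window selection, VAE pretraining and latent extraction."""
    stacks = {}
    for pre_vol, post_vol in studies:
        stacks[pre_vol.patient_id] = make_patient_stacks(pre_vol, post_vol)
    input_shape = stacks[next(iter(stacks))][0].lesion.shape[:3]
    common = dict(latent_dim=cfg.vae_latent, input_shape=tuple(input_shape),
                  hidden_widths=cfg.vae_hidden, epochs=cfg.vae_epochs,
                  seed=cfg.seed)
    vae1 = Vae(VaeConfig(input_channels=2, **common))
    vae2 = Vae(VaeConfig(input_channels=1, **common))
    if corpus is None:
        corpus = pretraining_corpus(cfg)
    hist1 = pretrain(vae1, corpus)
    hist2 = pretrain(vae2, corpus)
    mri_features = {pid: assemble_mri_features(pre, post, vae1, vae2,
                                               cfg.augment_scalars)
                    for pid, (pre, post) in stacks.items()}
    return mri_features, vae1, vae2, {"vae1": hist1, "vae2": hist2}


def _nn_builder(cfg: NnConfig, branch_columns=None):
    def build(X, y, fold_seed):
        return train_nn(X, y, dataclasses.replace(cfg, seed=fold_seed),
                        branch_columns=branch_columns)
    return build


def _mri_columns(fm: FeatureMatrix) -> np.ndarray:
    from .vae import GROUPS
    return np.array([j for j, g in enumerate(fm.feature_groups) if g in GROUPS],
                    dtype=int)


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full synthetic-cohort analysis; see module docstring."""
    clinical, studies = simulate_cohort(cfg.n_patients, cfg.outcome,
                                        cfg.cohort, cfg.seed)
    train_ids, test_ids = temporal_split(clinical)

    need_mri = any(m in ("mri", "multimodal") for m in cfg.modes)
    mri_features = vae1 = vae2 = None
    losses: dict[str, list[float]] = {}
    if need_mri:
        mri_features, vae1, vae2, losses = extract_cohort_features(studies, cfg)

    clinical_sorted = clinical.sort_values("patient_id").reset_index(drop=True)
    train_mask = clinical_sorted["patient_id"].astype(str).isin(train_ids).to_numpy()

    matrices: dict[str, FeatureMatrix] = {}
    cv_reports: dict[str, CvReport] = {}
    test_metrics: dict[str, dict] = {}
    for mode in cfg.modes:
        fm = build_matrix(clinical_sorted, mode, mri_features, train_mask)
        matrices[mode] = fm
        Xtr, ytr = fm.values[train_mask], fm.label[train_mask]
        Xte, yte = fm.values[~train_mask], fm.label[~train_mask]
        # the compression branch applies only where modalities are fused
        branch = _mri_columns(fm) if (mode == "multimodal"
                                      and cfg.nn.mri_branch_widths) else None
        cv_reports[mode] = repeated_cv(_nn_builder(cfg.nn, branch), Xtr, ytr,
                                       folds=cfg.folds, repeats=cfg.repeats,
                                       seed=cfg.seed, model_tag=mode)
        final = train_nn(Xtr, ytr, dataclasses.replace(cfg.nn, seed=cfg.seed),
                         fm.feature_names, branch_columns=branch)
        test_metrics[mode] = compute_metrics(yte, predict_proba(final, Xte))
        if mode == "multimodal":
            final_multimodal, fm_multi = final, fm

    for family in cfg.baselines:
        fm = matrices.get("multimodal") or build_matrix(
            clinical_sorted, "multimodal", mri_features, train_mask)
        Xtr, ytr = fm.values[train_mask], fm.label[train_mask]
        spec = GridSearchSpec(family=family, grid=DEFAULT_GRIDS[family])
        _, best = fit_baseline(Xtr, ytr, spec, cv_seed=cfg.seed)

        def builder(X, y, fold_seed, family=family, best=best):
            from .models import _FAMILIES
            est = _FAMILIES[family](fold_seed)
            est.set_params(**best)
            return est.fit(X, y)
        cv_reports[family] = repeated_cv(builder, Xtr, ytr, folds=cfg.folds,
                                         repeats=cfg.repeats, seed=cfg.seed,
                                         model_tag=family)

    comparisons: dict[str, dict] = {}
    if "multimodal" in cv_reports:
        ref = cv_reports["multimodal"].series("auc")
        for tag, rep in cv_reports.items():
            if tag == "multimodal":
                continue
            t, p = paired_t_test(ref, rep.series("auc"))
            comparisons[f"multimodal_vs_{tag}"] = {
                "t": t, "p": p,
                "mean_auc_multimodal": cv_reports["multimodal"].mean("auc"),
                f"mean_auc_{tag}": rep.mean("auc")}

    importance = None
    if "multimodal" in cfg.modes and cfg.n_permutations > 0:
        groups = feature_groups_from_columns(fm_multi.feature_groups)
        importance = grouped_permutation_importance(
            final_multimodal, fm_multi.values[~train_mask],
            fm_multi.label[~train_mask], groups,
            n_permutations=cfg.n_permutations, seed=cfg.seed)

    return StudyResult(clinical=clinical, train_ids=train_ids, test_ids=test_ids,
                       matrices=matrices, cv_reports=cv_reports,
                       test_metrics=test_metrics, comparisons=comparisons,
                       importance=importance, table1=build_table1(clinical),
                       vae1=vae1, vae2=vae2, loss_histories=losses)


# ---------------------------------------------------------------------------
# config-file / manifest layer

def config_from_dict(d: dict) -> StudyConfig:
    cfg = StudyConfig()
    if "cohort" in d:
        cfg.cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in d.pop("cohort").items()})
    if "outcome" in d:
        cfg.outcome = OutcomeModel(**d.pop("outcome"))
    if "nn" in d:
        nn = d.pop("nn")
        if "hidden_widths" in nn:
            nn["hidden_widths"] = tuple(nn["hidden_widths"])
        cfg.nn = NnConfig(**nn)
    for k, v in d.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
    return cfg


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _write_report(rep: CvReport, out_dir: Path, tag: str) -> list[str]:
    files = []
    cv_path = out_dir / f"cv_{tag}.csv"
    rep.to_frame().to_csv(cv_path, index=False)
    files.append(cv_path.name)
    grid, tpr = mean_roc_curve(rep.fold_scores)
    roc_path = out_dir / f"roc_{tag}.csv"
    pd.DataFrame({"fpr": grid, "mean_tpr": tpr}).to_csv(roc_path, index=False)
    files.append(roc_path.name)
    return files


def run_pipeline(config_path, out_dir, save_checkpoints: bool = False) -> Path:
    """Config-driven run with on-disk outputs and a manifest; returns out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = Path(config_path).read_text() if config_path else "{}"
    cfg = config_from_dict(yaml.safe_load(cfg_text) or {})

    t0 = time.time()
    result = run_study(cfg)

    artifacts: list[str] = []
    write_clinical_csv(result.clinical, out_dir / "clinical.csv")
    artifacts.append("clinical.csv")
    for tag, rep in result.cv_reports.items():
        artifacts += _write_report(rep, out_dir, tag)
    summary = {
        "cv_mean_auc": {t: r.mean("auc") for t, r in result.cv_reports.items()},
        "cv_std_auc": {t: r.std("auc") for t, r in result.cv_reports.items()},
        "test_metrics": result.test_metrics,
        "comparisons": result.comparisons,
        "split": {"n_train": len(result.train_ids), "n_test": len(result.test_ids)},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    artifacts.append("summary.json")
    if result.importance is not None:
        result.importance.to_csv(out_dir / "importance.csv", index=False)
        artifacts.append("importance.csv")
    result.table1.to_csv(out_dir / "table1.csv", index=False)
    (out_dir / "table1.md").write_text(table1_markdown(result.table1))
    artifacts += ["table1.csv", "table1.md"]
    if save_checkpoints and result.vae1 is not None:
        save_checkpoint(result.vae1, out_dir / "vae1.npz")
        save_checkpoint(result.vae2, out_dir / "vae2.npz")
        artifacts += ["vae1.npz", "vae2.npz"]

    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": _version(),
        "artifacts": artifacts,
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("kpsfusion")
    except PackageNotFoundError:
        return "unknown"
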