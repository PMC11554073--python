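"""KPS classifiers: the neural network and grid-searched baseline models.

The reference classifier is a small dense network with a two-neuron softmax
output for the binary endpoint (KPS < 70 vs >= 70), trained with Adam on
cross-entropy; optional 'balanced' class weighting reweights samples inversely
to class frequency. Baselines are tree ensembles tuned by exhaustive grid
search with inner stratified CV on AUC. Gradient-boosting families stand in
for the usual XGBoost/LightGBM implementations, which are not available here.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (GradientBoostingClassifier,
                              HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from ._nn import Adam, SoftmaxNet


@dataclass
class NnConfig:
    hidden_widths: tuple[int, ...] = (64, 32)
    dropout: float = 0.3
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.0  # decoupled L2 on weight matrices
    mri_branch_widths: tuple[int, ...] = ()  # bottleneck branch for MRI columns
    seed: int = 0
    class_weighting: str = "none"  # {"none", "balanced"}


class KpsNet:
    """Trained neural-network classifier (feature order is part of the contract)."""

    def __init__(self, net: SoftmaxNet, feature_names: list[str],
                 config: NnConfig, loss_history: list[float]):
        self.net = net
        self.feature_names = list(feature_names)
        self.config = config
        self.loss_history = loss_history

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "KpsNet":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_nn(X: np.ndarray, y: np.ndarray, config: NnConfig | None = None,
             feature_names: list[str] | None = None,
             branch_columns=None) -> KpsNet:
    """Train the softmax network; deterministic given the config seed.

    ``branch_columns`` (with ``config.mri_branch_widths`` nonempty) routes the
    named column indices through a compression branch before fusion.
    """
    config = config or NnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    if config.class_weighting == "balanced":
        w_class = len(y) / (2.0 * np.bincount(y, minlength=2))
        weights = w_class[y]
    elif config.class_weighting == "none":
        weights = np.ones(len(y))
    else:
        raise ValueError(f"unknown class_weighting {config.class_weighting!r}")

    rng = np.random.default_rng(config.seed)
    use_branch = branch_columns is not None and len(config.mri_branch_widths) > 0
    net = SoftmaxNet([X.shape[1], *config.hidden_widths, 2], rng,
                     dropout=config.dropout,
                     branch_columns=branch_columns if use_branch else None,
                     branch_sizes=list(config.mri_branch_widths) if use_branch else None)
    opt = Adam(net.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    onehot = np.eye(2)[y]
    n = len(y)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            loss, grads = net.loss_and_grads(X[idx], onehot[idx], weights[idx], rng)
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    names = feature_names if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])]
    return KpsNet(net, names, config, history)


def predict_proba(model, X: np.ndarray,
                  feature_names: list[str] | None = None) -> np.ndarray:
    """Positive-class (KPS < 70) probability for each row.

    Works for both :class:`KpsNet` and the sklearn baselines. If feature
    names are given they must match the training-time names and order.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    if isinstance(model, KpsNet):
        if feature_names is not None and list(feature_names) != model.feature_names:
            bad = [f"{a!r} (trained on {b!r})" for a, b
                   in zip(feature_names, model.feature_names) if a != b]
            raise ValueError(f"feature columns differ from training: {bad[:5]}")
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}")
        return model.net.predict_proba(X)[:, 1]
    return model.predict_proba(X)[:, 1]


@dataclass
class GridSearchSpec:
    family: str  # {"random_forest", "gradient_boosting", "hist_gradient_boosting"}
    grid: dict[str, list] = field(default_factory=dict)
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("parameter grid must be nonempty")


_FAMILIES = {
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "hist_gradient_boosting": lambda seed: HistGradientBoostingClassifier(random_state=seed),
}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 4]},
    "gradient_boosting": {"n_estimators": [100, 200], "learning_rate": [0.05, 0.1],
                          "max_depth": [2, 3]},
    "hist_gradient_boosting": {"max_iter": [100, 200], "learning_rate": [0.05, 0.1],
                               "max_depth": [None, 3]},
}


def fit_baseline(X: np.ndarray, y: np.ndarray, spec: GridSearchSpec,
                 cv_seed: int = 0):
    """Exhaustive grid search (inner stratified CV, AUC) and refit on all data.

    Returns ``(fitted estimator, best_params)``.
    """
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown baseline family {spec.family!r}; "
                         f"choose from {sorted(_FAMILIES)}")
    base = _FAMILIES[spec.family](cv_seed)
    cv = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=cv_seed)
    gs = GridSearchCV(base, spec.grid, scoring="roc_auc", cv=cv, refit=True)
    gs.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return gs.best_estimator_, dict(gs.best_params_)
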