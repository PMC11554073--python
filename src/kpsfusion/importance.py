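"""Grouped permutation feature importance.

Importance of an expert-defined feature group is the drop in a performance
metric (AUC by default) when all of the group's columns are jointly shuffled
with the same row permutation — preserving within-group correlation while
breaking the group's association with the outcome. MRI latent features form
four groups (pre/post × lesion/mask); each clinical parameter is its own
group. Negative importances are reported as-is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import compute_metrics
from .models import predict_proba


def feature_groups_from_columns(feature_groups: list[str]) -> dict[str, list[int]]:
    """Column indices per group, in first-appearance order; groups partition columns."""
    out: dict[str, list[int]] = {}
    for j, g in enumerate(feature_groups):
        out.setdefault(g, []).append(j)
    return out


def grouped_permutation_importance(model, X: np.ndarray, labels: np.ndarray,
                                   groups: dict[str, list[int]] | list[str],
                                   n_permutations: int = 30, seed: int = 0,
                                   metric: str = "auc") -> pd.DataFrame:
    """Importance table, sorted descending by mean importance.

    ``groups`` maps group name -> column indices (or is a per-column group
    list). Returns columns: group, importance (baseline − mean permuted
    score), std (over permutation rounds), n_columns.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    if isinstance(groups, (list, tuple)):
        groups = feature_groups_from_columns(list(groups))
    p = X.shape[1]
    for name, cols in groups.items():
        if any(c < 0 or c >= p for c in cols):
            raise ValueError(f"group {name!r} references unknown column index")

    rng = np.random.default_rng(seed)
    baseline = compute_metrics(labels, predict_proba(model, X))[metric]
    rows = []
    for name, cols in groups.items():
        drops = np.empty(n_permutations)
        for r in range(n_permutations):
            perm = rng.permutation(X.shape[0])  # one shared row permutation
            Xp = X.copy()
            Xp[:, cols] = Xp[perm][:, cols]
            drops[r] = compute_metrics(labels, predict_proba(model, Xp))[metric]
        rows.append({"group": name, "importance": baseline - drops.mean(),
                     "std": drops.std(ddof=1) if n_permutations > 1 else 0.0,
                     "n_columns": len(cols)})
    table = pd.DataFrame(rows).sort_values("importance", ascending=False,
                                           kind="mergesort").reset_index(drop=True)
    table.attrs["baseline"] = baseline
    table.attrs["metric"] = metric
    return table
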