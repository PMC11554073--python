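"""Baseline-characteristics table split by the 6-month KPS outcome.

Categorical parameters are shown as count (%) per outcome group with a
Fisher's exact p-value (Freeman–Halton for multi-level parameters);
continuous parameters as median (range) with a Mann–Whitney U p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from .stats import fisher_exact_2x2, fisher_exact_rxc, format_p, mann_whitney_u


def _cat_row(name: str, pos_vals, neg_vals, level) -> dict:
    n_pos, n_neg = len(pos_vals), len(neg_vals)
    a = int((pos_vals == level).sum())
    b = int((neg_vals == level).sum())
    return {"parameter": name,
            "kps_lt70": f"{a} ({100 * a / n_pos:.1f})",
            "kps_ge70": f"{b} ({100 * b / n_neg:.1f})"}


def _cont_row(name: str, pos_vals, neg_vals) -> dict:
    def fmt(v):
        return (f"{np.median(v):g} ({np.min(v):g}-{np.max(v):g})")
    return {"parameter": name, "kps_lt70": fmt(pos_vals), "kps_ge70": fmt(neg_vals)}


def build_table1(clinical: pd.DataFrame) -> pd.DataFrame:
    """Formatted baseline table with per-parameter exact-test p-values."""
    df = clinical.copy()
    pos = pd.to_numeric(df[schema.ENDPOINT]) < 70
    rows: list[dict] = []

    for param in schema.CLINICAL_PARAMS:
        pv, nv = df.loc[pos, param], df.loc[~pos, param]
        if param in schema.CONTINUOUS_PARAMS:
            row = _cont_row(param, pd.to_numeric(pv).to_numpy(),
                            pd.to_numeric(nv).to_numpy())
            _, p = mann_whitney_u(pd.to_numeric(pv), pd.to_numeric(nv))
            row["p_value"] = format_p(p)
            row["test"] = "mann_whitney_u"
            rows.append(row)
        elif param in ("laterality", "extent_of_resection"):
            levels = (schema.LATERALITY_LEVELS if param == "laterality"
                      else schema.EXTENT_LEVELS)
            table = np.array([[(pv == lv).sum() for lv in levels],
                              [(nv == lv).sum() for lv in levels]], dtype=int)
            keep = table.sum(axis=0) > 0  # drop empty levels before testing
            res = fisher_exact_rxc(table[:, keep])
            for i, lv in enumerate(levels):
                row = _cat_row(f"{param}={lv}", pv, nv, lv)
                row["p_value"] = format_p(res["p"]) if i == 0 else "-"
                row["test"] = "fisher_exact_rxc" if i == 0 else ""
                rows.append(row)
        else:  # binary
            pvn, nvn = pd.to_numeric(pv), pd.to_numeric(nv)
            table = [[int((pvn == 1).sum()), int((pvn == 0).sum())],
                     [int((nvn == 1).sum()), int((nvn == 0).sum())]]
            p, _ = fisher_exact_2x2(table)
            row = _cat_row(param, pvn, nvn, 1)
            row["p_value"] = format_p(p)
            row["test"] = "fisher_exact_2x2"
            rows.append(row)

    out = pd.DataFrame(rows)
    out.attrs["n_kps_lt70"] = int(pos.sum())
    out.attrs["n_kps_ge70"] = int((~pos).sum())
    return out


def table1_markdown(table: pd.DataFrame) -> str:
    n1, n0 = table.attrs.get("n_kps_lt70", "?"), table.attrs.get("n_kps_ge70", "?")
    lines = [f"| Parameter | KPS < 70 (n={n1}) | KPS >= 70 (n={n0}) | P value |",
             "|---|---|---|---|"]
    for _, r in table.iterrows():
        lines.append(f"| {r['parameter']} | {r['kps_lt70']} | {r['kps_ge70']} "
                     f"| {r['p_value']} |")
    return "\n".join(lines)
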