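"""Univariate cohort statistics: exact tests for the baseline table.

Categorical parameters are tested with Fisher's exact test (two-sided by the
point-probability rule; the Freeman–Halton generalisation for r×c tables),
continuous ones with the Mann–Whitney U test (exact enumeration with midrank
ties for small samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

EXACT_MWU_MAX_N = 12
RXC_ENUM_LIMIT = 10_000_000


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table.

    Returns ``(p, odds_ratio)``. The two-sided p sums hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed one (the convention of
    mainstream scientific software). A degenerate margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin; p = 1")
        a, b, c, d = t.ravel()
        orat = (a * d) / (b * c) if b * c > 0 else np.inf
        return 1.0, float(orat)
    orat, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p), float(orat)


def _rxc_enum_size(row_sums, n_cols) -> int:
    """Upper bound on the number of tables with the given row margins."""
    size = 1
    for r in row_sums[:-1]:
        size *= math.comb(r + n_cols - 1, n_cols - 1)
        if size > RXC_ENUM_LIMIT:
            return size
    return size


def _log_table_prob(t: np.ndarray, lgf: np.ndarray) -> float:
    """log multivariate hypergeometric probability given both margins."""
    rs, cs = t.sum(axis=1), t.sum(axis=0)
    return (lgf[rs].sum() + lgf[cs].sum() - lgf[t.sum()] - lgf[t].sum())


def fisher_exact_rxc(table, n_mc: int = 200_000, seed: int = 0):
    """Freeman–Halton exact test for an r×c table.

    Exhaustive enumeration of all tables with the observed margins when
    feasible; otherwise Monte-Carlo with fixed margins (reported via the
    returned dict: ``{"p", "method", "se"}``).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2D table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin; p = 1")
        return {"p": 1.0, "method": "degenerate", "se": 0.0}
    rows, cols = t.shape
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    lgf = gammaln(np.arange(t.sum() + 2) + 1.0)  # log factorials

    logp_obs = _log_table_prob(t, lgf)
    tol = 1e-9

    if _rxc_enum_size(row_sums, cols) <= RXC_ENUM_LIMIT:
        total = 0.0
        extreme = 0.0

        def rec(row: int, remaining_cols: np.ndarray, built: list[np.ndarray]):
            nonlocal total, extreme
            if row == rows - 1:
                last = remaining_cols
                if (last < 0).any() or last.sum() != row_sums[-1]:
                    return
                cand = np.vstack(built + [last])
                lp = _log_table_prob(cand, lgf)
                pr = math.exp(lp)
                total += pr
                if lp <= logp_obs + tol:
                    extreme += pr
                return
            for combo in _compositions(row_sums[row], cols):
                c = np.array(combo)
                if (c > remaining_cols).any():
                    continue
                rec(row + 1, remaining_cols - c, built + [c])

        rec(0, col_sums.copy(), [])
        return {"p": min(1.0, extreme / total), "method": "enumeration", "se": 0.0}

    # Monte-Carlo over tables with fixed margins (Patefield-style sampling via
    # permutation of category labels)
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(rows), row_sums)
    col_labels = np.repeat(np.arange(cols), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        cand = np.zeros((rows, cols), dtype=int)
        np.add.at(cand, (row_labels, perm), 1)
        if _log_table_prob(cand, lgf) <= logp_obs + tol:
            hits += 1
    p = hits / n_mc
    se = math.sqrt(p * (1 - p) / n_mc)
    warnings.warn(f"enumeration bound exceeded; Monte-Carlo p with se={se:.2e}")
    return {"p": p, "method": "monte_carlo", "se": se}


def _compositions(total: int, k: int):
    """All k-part compositions of ``total`` (weak, ordered)."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, k - 1):
            yield (first,) + rest


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U for group a, midrank ties."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:len(a)].sum() - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann–Whitney U (group a) with two-sided p.

    Exact enumeration over all group assignments when n_a + n_b <= 12
    (valid under ties via midranks); otherwise scipy's normal approximation
    with tie correction and continuity correction. All-identical values give
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return u, 1.0
    na, n = len(a), len(pooled)
    if n <= EXACT_MWU_MAX_N:
        mean_u = na * (n - na) / 2.0
        obs_dev = abs(u - mean_u)
        count = 0
        totals = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            totals += 1
            if abs(u_perm - mean_u) >= obs_dev - 1e-9:
                count += 1
        return u, count / totals
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def format_p(p: float) -> str:
    """Display rounding: 2 decimals, 3 when p < 0.01, '<0.001' below that."""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"
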