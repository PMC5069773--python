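"""Shared rank-based test utilities.

Wraps scipy/statsmodels for the standard tests and implements Dunn's
post-hoc z-test (no pre-installed package provides it).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "dunn_test", "mannwhitney_u", "mannwhitney_table"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def dunn_test(groups: dict, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests on joint ranks.

    Standard follow-up to a Kruskal-Wallis omnibus test: observations
    from all groups are ranked together (mid-ranks for ties), and for
    each pair the difference in mean rank is compared against its null
    standard error with a tie correction,

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1))

    where t runs over tie-group sizes.  Two-sided p-values are BH
    adjusted across pairs.

    Returns a DataFrame with one row per pair: group_a, group_b, z, p,
    p_adjusted.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(values)
    n_total = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + v.size].mean()
        sizes[name] = v.size
        start += v.size

    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = bh_adjust(out["p"])
    else:
        out["p_adjusted"] = out["p"]
    return out


def mannwhitney_u(a, b, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both samples are small (``n <= exact_max_n``)
    and tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Degenerate all-tied data returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def mannwhitney_table(X: np.ndarray, group_a_cols, group_b_cols) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values for a feature x sample matrix.

    Uses the tie-corrected normal approximation (rounded-proportion data
    always carries ties, so the exact distribution does not apply).
    Constant rows are returned as p = 1.
    """
    X = np.asarray(X, dtype=float)
    a = X[:, group_a_cols]
    b = X[:, group_b_cols]
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=1).pvalue
    constant = np.all(X == X[:, [0]], axis=1)
    p = np.where(constant, 1.0, p)
    return np.nan_to_num(p, nan=1.0)
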