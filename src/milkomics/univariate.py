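"""Univariate group comparison with FDR control.

Per-feature Mann-Whitney U tests between the two growth groups with
Benjamini-Hochberg adjustment across each block, plus the
median (P25-P75) summaries the result tables report.  Weeks 2-4 are
pooled as independent observations by default, mirroring the study's
tables; a per-mother-mean mode is available for sensitivity analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_COMBINED_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (full enumeration) when the combined sample
    size is <= 12 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MAX_COMBINED_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min over j >= i of (m * p(j) / j) on the sorted p-values,
    mapped back to the input order.  NaN inputs propagate as NaN with a
    warning and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)
    if (~valid).any():
        warnings.warn(f"bh_fdr: {int((~valid).sum())} NaN p-value(s) propagated")
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def significance_tier(q: float) -> str:
    """Tier glyph used in the result tables: ** (<0.01), * (<0.05),
    t (trend, <0.1), '' otherwise."""
    if np.isnan(q):
        return ""
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    if q < 0.1:
        return "t"
    return ""


def group_summary(values, groups) -> pd.DataFrame:
    """Median and quartiles (linear interpolation) per group.

    Returns a DataFrame indexed by group with columns median/p25/p75 and
    a pre-formatted ``"median (P25-P75)"`` string.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        med, p25, p75 = np.percentile(v, [50, 25, 75])
        rows[g] = {
            "median": med,
            "p25": p25,
            "p75": p75,
            "formatted": f"{med:.4g} ({p25:.4g}–{p75:.4g})",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_univariate_screen(X: pd.DataFrame, groups,
                          group_order=("slower", "faster")) -> pd.DataFrame:
    """Feature-wise Mann-Whitney screen with BH-FDR across the block.

    ``X`` is an observation x feature DataFrame (original abundance
    units, pooled over weeks); ``groups`` the per-observation growth
    label.  Returns one row per feature with group summaries, U, p, q
    and the significance tier.
    """
    groups = np.asarray(groups)
    present = [g for g in group_order if (groups == g).any()]
    if len(present) != 2:
        raise ValueError(f"expected both groups {group_order}, found {present}")
    g_a, g_b = present
    records = []
    for fid in X.columns:
        v = X[fid].to_numpy(dtype=float)
        u, p = mann_whitney(v[groups == g_a], v[groups == g_b])
        summ = group_summary(v, groups)
        records.append({
            "feature_id": fid,
            f"median_{g_a}": summ.loc[g_a, "formatted"],
            f"median_{g_b}": summ.loc[g_b, "formatted"],
            "U": u,
            "mw_p": p,
        })
    out = pd.DataFrame(records).set_index("feature_id")
    out["mw_q"] = bh_fdr(out["mw_p"].to_numpy())
    out["tier"] = [significance_tier(q) for q in out["mw_q"]]
    return out
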