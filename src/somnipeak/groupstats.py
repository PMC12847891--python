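"""Nonparametric group statistics on component scores.

For every component (per channel, condition, histogram kind and method) the
five diagnostic groups are compared with a Kruskal-Wallis test; the family
of Kruskal-Wallis p-values within one component set is corrected with the
Benjamini-Yekutieli false-discovery-rate procedure at alpha = 0.1 (valid
under arbitrary dependence, harmonic-sum correction c(m) = sum 1/i). Where
the corrected test survives, post hoc two-sided Mann-Whitney U tests compare
controls against each patient group with Bonferroni adjustment over the
patient contrasts (p <= 0.05). Effect size is reported as the
Kruskal-Wallis eta squared, eta2_H = (H - k + 1)/(n - k), which can be
slightly negative under the null and is reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "by_fdr",
    "mannwhitney_posthoc",
    "eta_squared",
    "run_group_stats",
]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations equal is a degenerate case with no evidence against the
    null: returns (0.0, 1.0) rather than propagating the division by zero.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def by_fdr(p_values: np.ndarray, alpha: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR control.

    Returns (reject flags, adjusted p-values). Rejections are monotone: if a
    p-value is rejected, every smaller one is too.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return reject, p_adj


def mannwhitney_posthoc(control: np.ndarray, patients: dict,
                        m_comparisons: int | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of controls vs each patient group.

    Exact p-values for small tie-free samples (both n <= 8), the
    tie/continuity-corrected normal approximation otherwise (scipy's 'auto'
    policy). Bonferroni multiplies by the number of patient contrasts.
    """
    control = np.asarray(control, dtype=float)
    m = m_comparisons if m_comparisons is not None else len(patients)
    rows = []
    for name, vals in patients.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0 or len(control) == 0:
            rows.append({"group": name, "U": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "significant": False,
                         "skipped": True})
            continue
        pooled = np.concatenate([control, vals])
        if np.all(pooled == pooled[0]):
            U, p = len(control) * len(vals) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(control, vals, alternative="two-sided",
                                     method="auto")
            U, p = float(res.statistic), float(res.pvalue)
        p_bonf = min(1.0, p * m)
        rows.append({"group": name, "U": U, "p_raw": p, "p_bonferroni": p_bonf,
                     "significant": bool(p_bonf <= alpha), "skipped": False})
    return pd.DataFrame(rows)


def eta_squared(H: float, k: int, n: int) -> float:
    """Kruskal-Wallis effect size eta2_H = (H - k + 1) / (n - k)."""
    if n <= k:
        raise ValueError("need more observations than groups")
    return (H - k + 1) / (n - k)


@dataclass
class StatsFamily:
    """Full cascade for one component set (one FDR family)."""

    table: pd.DataFrame              # one row per component
    pairwise: dict                   # component index -> posthoc DataFrame


def run_group_stats(scores: np.ndarray, group_labels: list[str],
                    control: str = "control", alpha_fdr: float = 0.1,
                    alpha_pairwise: float = 0.05,
                    posthoc_gate: bool = True) -> StatsFamily:
    """Kruskal-Wallis + BY FDR + gated Mann-Whitney cascade on one score matrix.

    ``scores`` is subjects x components; the FDR family is the component set.
    """
    labels = np.asarray(group_labels)
    names = list(dict.fromkeys(group_labels))
    if control not in names:
        raise ValueError(f"control group {control!r} absent")
    k = len(names)
    n = len(labels)
    groups_idx = {g: labels == g for g in names}

    rows = []
    for c in range(scores.shape[1]):
        gvals = [scores[groups_idx[g], c] for g in names]
        H, p = kruskal_wallis(gvals)
        rows.append({"component": c, "H": H, "p_raw": p,
                     "eta_sq": eta_squared(H, k, n)})
    table = pd.DataFrame(rows)
    reject, p_adj = by_fdr(table["p_raw"].to_numpy(), alpha_fdr)
    table["p_fdr"] = p_adj
    table["fdr_rejected"] = reject

    pairwise = {}
    patients = {g: None for g in names if g != control}
    for c in range(scores.shape[1]):
        if posthoc_gate and not table.loc[c, "fdr_rejected"]:
            continue
        pat = {g: scores[groups_idx[g], c] for g in patients}
        pairwise[c] = mannwhitney_posthoc(scores[groups_idx[control], c], pat,
                                          m_comparisons=len(pat),
                                          alpha=alpha_pairwise)
    return StatsFamily(table, pairwise)
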