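"""Rank-based group comparison implemented from the defining formulas:
Kruskal-Wallis omnibus test with tie correction and Dunn's pairwise post hoc
z-tests with Bonferroni correction and significance-tier labels."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "GroupData",
    "TestReport",
    "SIGNIFICANCE_TIERS",
    "kruskal_wallis",
    "dunn_posthoc",
    "tier_label",
]

# threshold -> label, checked in ascending-threshold order
SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


@dataclass
class GroupData:
    """Named groups of real observations."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float).ravel()
                       for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.groups.items():
            if vals.size < 1:
                raise ValueError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} contains non-finite values")

    @property
    def names(self) -> list[str]:
        return list(self.groups.keys())

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.groups[k] for k in self.names])

    def sizes(self) -> np.ndarray:
        return np.array([self.groups[k].size for k in self.names])


@dataclass
class TestReport:
    h_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj, tier


def _tie_term(pooled: np.ndarray) -> float:
    """Sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def tier_label(p_adj: float) -> str:
    for threshold, label in SIGNIFICANCE_TIERS:
        if p_adj < threshold:
            return label
    return "ns"


def kruskal_wallis(data: GroupData) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 dof).

    All-identical observations give H = 0, p = 1 rather than an error.
    """
    pooled = data.pooled()
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(pooled)
    sizes = data.sizes()
    k = len(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_rank = (n_total + 1) / 2.0
    h = 0.0
    for i in range(k):
        ri = ranks[bounds[i]:bounds[i + 1]].mean()
        h += sizes[i] * (ri - mean_rank) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:  # every observation identical
        return 0.0, 1.0
    h /= correction
    return float(h), float(chi2.sf(h, k - 1))


def dunn_posthoc(data: GroupData) -> TestReport:
    """Dunn's pairwise z-tests on pooled mid-ranks with the tie-corrected
    variance, two-sided normal p-values, and Bonferroni adjustment over all
    k(k-1)/2 pairs."""
    names = data.names
    if len(names) < 2:
        raise ValueError("post hoc comparison needs at least 2 groups")
    pooled = data.pooled()
    n_total = pooled.size
    ranks = rankdata(pooled)
    sizes = data.sizes()
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        name: ranks[bounds[i]:bounds[i + 1]].mean()
        for i, name in enumerate(names)
    }
    n_by_name = dict(zip(names, sizes))
    tie = _tie_term(pooled)
    var_term = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))

    h, p_omni = kruskal_wallis(data)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        denom_sq = var_term * (1.0 / n_by_name[a] + 1.0 / n_by_name[b])
        if denom_sq <= 0:  # all observations tied
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(denom_sq)
        p_raw = 2.0 * norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append({
            "group_a": a, "group_b": b, "z": float(z),
            "p_raw": float(p_raw), "p_adj": float(p_adj),
            "tier": tier_label(p_adj),
        })
    return TestReport(h_statistic=h, omnibus_p=p_omni,
                      pairwise=pd.DataFrame(rows))
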