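"""Group-level descriptive statistics and nonparametric comparisons.

Per-AZ and per-image quantities in this pipeline (localization counts,
areas, radii) are heavily skewed, so groups are described as
median (25th-75th percentile) and compared with the Kruskal-Wallis
one-way ANOVA on ranks followed by Dunn's pairwise z-comparisons.
Shapiro-Wilk normality p-values are reported per group to justify the
rank-based route.

Dunn's z statistic for groups i, j uses the pooled mid-ranks:

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )

with tie correction T = sum(t³ - t) / (12 (N - 1)); two-sided p-values
come from the standard normal.  The multiple-comparison adjustment is
configurable ("none" — Dunn's plain z comparison — or "bonferroni").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "summarize",
    "dunn_test",
    "compare_groups",
]


def summarize(values) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    vals = np.asarray(values, float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty sample")
    return (float(np.median(vals)),
            float(np.percentile(vals, 25)),
            float(np.percentile(vals, 75)))


@dataclass
class GroupComparison:
    """Descriptives, omnibus and pairwise test results for >= 2 groups."""

    names: list[str]
    descriptives: pd.DataFrame           # median, q25, q75, n per group
    shapiro_p: dict[str, float]
    kw_statistic: float
    kw_p: float
    dunn_p: pd.DataFrame                 # symmetric pairwise matrix
    alpha_level: float = 0.05
    adjust: str = "none"
    testable: bool = True

    @property
    def significant(self) -> bool:
        return self.testable and self.kw_p < self.alpha_level

    def significant_pairs(self) -> list[tuple[str, str]]:
        out = []
        for a, b in itertools.combinations(self.names, 2):
            if self.testable and self.dunn_p.loc[a, b] < self.alpha_level:
                out.append((a, b))
        return out

    def summary(self) -> str:
        lines = ["Group comparison (Kruskal-Wallis + Dunn)", "-" * 41]
        for name, row in self.descriptives.iterrows():
            lines.append(f"{name:<10} median {row['median']:.4g} "
                         f"({row['q25']:.4g}-{row['q75']:.4g}), n={int(row['n'])}, "
                         f"Shapiro-Wilk p={self.shapiro_p[name]:.3g}")
        if not self.testable:
            lines.append("omnibus: not testable (degenerate/tied data)")
            return "\n".join(lines)
        lines.append(f"ANOVA on ranks: H = {self.kw_statistic:.4g}, "
                     f"p = {self.kw_p:.3g}")
        for a, b in itertools.combinations(self.names, 2):
            p = self.dunn_p.loc[a, b]
            flag = "*" if p < self.alpha_level else " "
            lines.append(f"  {a} vs {b}: p = {p:.3g} {flag}")
        return "\n".join(lines)


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "none") -> pd.DataFrame:
    """Dunn's pairwise z comparisons on pooled mid-ranks (tie-corrected).

    ``adjust`` is ``"none"`` (plain two-sided z p-values) or
    ``"bonferroni"`` (multiplied by the number of pairs, capped at 1).
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    names = list(groups)
    sizes = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = stats.rankdata(pooled)
    big_n = len(pooled)

    mean_ranks, start = {}, 0
    for k in names:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (big_n - 1))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term

    n_pairs = len(names) * (len(names) - 1) // 2
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def compare_groups(groups: dict[str, np.ndarray], alpha_level: float = 0.05,
                   adjust: str = "none") -> GroupComparison:
    """Shapiro-Wilk per group, Kruskal-Wallis omnibus, Dunn pairwise.

    Requires >= 2 groups with >= 3 values each.  Data sets in which all
    pooled values are identical are reported as non-testable (omnibus
    p = 1) rather than raising.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 values")

    names = list(groups)
    desc = pd.DataFrame(
        [(*summarize(groups[k]), len(groups[k])) for k in names],
        index=names, columns=["median", "q25", "q75", "n"])

    shapiro_p = {}
    for k in names:
        vals = np.asarray(groups[k], float)
        if np.ptp(vals) == 0:
            shapiro_p[k] = float("nan")
        else:
            shapiro_p[k] = float(stats.shapiro(vals).pvalue)

    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    if np.ptp(pooled) == 0:
        dunn = pd.DataFrame(np.ones((len(names), len(names))),
                            index=names, columns=names)
        return GroupComparison(names, desc, shapiro_p, float("nan"), 1.0,
                               dunn, alpha_level, adjust, testable=False)

    kw = stats.kruskal(*(groups[k] for k in names))
    dunn = dunn_test(groups, adjust=adjust)
    return GroupComparison(names, desc, shapiro_p, float(kw.statistic),
                           float(kw.pvalue), dunn, alpha_level, adjust)
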