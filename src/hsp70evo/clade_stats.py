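"""Nonparametric clade comparison: Kruskal–Wallis, pairwise Wilcoxon with
Holm adjustment, Cohen's d, and a compact letter display.

Pooled Ka/Ks ratios are bounded, skewed and clade sample sizes are unequal,
so comparisons are rank-based throughout: an omnibus Kruskal–Wallis test
(chi-squared approximation, tie-corrected), pairwise two-sided rank-sum tests
with the Holm step-down family-wise correction, and |Cohen's d| as the
standardized effect size (values above 0.8 read as large by the usual
convention).  Each statistic is computed from its defining formula; scipy
supplies only the rank transform and the reference distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
LARGE_D = 0.8


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """(H, df, p) for k groups via ranks of the pooled sample.

    H = 12/(n(n+1)) * sum(R_g^2/n_g) - 3(n+1), divided by the tie correction
    1 - sum(t^3 - t)/(n^3 - n); p comes from chi-squared with k-1 df.  When
    every observation is identical the tie divisor vanishes and H is 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        rg = ranks[start:start + size].sum()
        h += rg * rg / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_div = 1.0 - float(((counts ** 3 - counts).sum()) / (n ** 3 - n))
    h = 0.0 if tie_div == 0 else h / tie_div
    df = len(groups) - 1
    return float(h), df, float(sps.chi2.sf(h, df))


# ---------------------------------------------------------------------------
# rank-sum test


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p via the null distribution of W.

    Enumerates the distribution of the rank sum of the smaller-indexed group
    by dynamic programming over which ranks it occupies (valid without ties).
    """
    nx_, ny_ = len(x), len(y)
    n = nx_ + ny_
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:nx_].sum()
    # counts[k][s] = number of k-subsets of {1..n} with rank sum s
    max_sum = n * (n + 1) // 2
    counts = np.zeros((nx_ + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, nx_), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1, :]
    dist = counts[nx_]
    total = dist.sum()
    w_int = int(round(w))
    p_le = dist[: w_int + 1].sum() / total
    p_ge = dist[w_int:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def ranksum_p(group_a: Sequence[float], group_b: Sequence[float],
              exact_max: int = 10) -> float:
    """Two-sided rank-sum (Wilcoxon/Mann-Whitney) p-value.

    Exact enumeration when both groups have at most *exact_max* observations
    and the pooled values are tie-free; otherwise the normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(x) <= exact_max and len(y) <= exact_max:
        return _exact_ranksum_p(x, y)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    w = ranks[: len(x)].sum()
    mu = len(x) * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / ((n) * (n - 1))
    var = len(x) * len(y) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# Holm adjustment and letters


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment: sorted raw p times (m - rank + 1), made
    monotone nondecreasing along the sorted order and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compact_letter_display(labels: Sequence[str], adj_p: pd.DataFrame,
                           alpha: float = ALPHA) -> dict[str, str]:
    """Letters such that two groups share a letter iff adj p >= alpha.

    Maximal cliques of the non-significance graph each receive one letter
    (presentation layer only; the adjusted p matrix is the inference).
    """
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, b in itertools.combinations(labels, 2):
        p = adj_p.loc[a, b]
        if not np.isnan(p) and p >= alpha:
            g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: (min(labels.index(x) for x in c), sorted(c)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for lab in clique:
            letters[lab].append(letter)
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def pairwise_wilcoxon_holm(groups: Mapping[str, Sequence[float]],
                           alpha: float = ALPHA
                           ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Holm-adjusted pairwise rank-sum p matrix plus compact letters.

    The matrix is symmetric with a unit diagonal; pairs involving a group of
    fewer than two observations carry NaN.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(labels, 2))
    raw = [ranksum_p(groups[a], groups[b]) for a, b in pairs]
    defined = [i for i, p in enumerate(raw) if not math.isnan(p)]
    adj = [float("nan")] * len(raw)
    adj_defined = holm_adjust([raw[i] for i in defined])
    for i, v in zip(defined, adj_defined):
        adj[i] = v
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat, compact_letter_display(labels, mat, alpha)


# ---------------------------------------------------------------------------
# effect size


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """|Cohen's d| with the pooled sample standard deviation.

    Zero when both groups are constant with equal means; infinite when the
    pooled variance vanishes but the means differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    diff = abs(a.mean() - b.mean())
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / math.sqrt(pooled))


# ---------------------------------------------------------------------------
# report


@dataclass
class StatsReport:
    """Full clade comparison: omnibus test, pairwise tests, effect sizes."""

    kw_statistic: float
    kw_df: int
    kw_p: float
    adjusted_p: pd.DataFrame
    effect_sizes: pd.DataFrame
    letters: dict[str, str]
    large_pairs: list[tuple[str, str]]
    group_sizes: dict[str, int]

    def to_text(self) -> str:
        lines = [
            f"Kruskal-Wallis chi-squared = {self.kw_statistic:.3f}, "
            f"df = {self.kw_df}, p = {self.kw_p:.3g}",
            "groups: " + ", ".join(
                f"{g} (n={n}, letters={self.letters[g]})"
                for g, n in self.group_sizes.items()
            ),
            "large effects (|d| > 0.8): "
            + (", ".join(f"{a}-{b}" for a, b in self.large_pairs) or "none"),
        ]
        return "\n".join(lines)

    def to_tables(self) -> dict[str, pd.DataFrame]:
        omnibus = pd.DataFrame(
            [{"statistic": self.kw_statistic, "df": self.kw_df, "p": self.kw_p}]
        )
        letters = pd.DataFrame(
            [{"group": g, "n": self.group_sizes[g], "letters": l}
             for g, l in self.letters.items()]
        )
        return {
            "omnibus": omnibus,
            "pairwise_adjusted_p": self.adjusted_p,
            "effect_sizes": self.effect_sizes,
            "letters": letters,
        }


def clade_comparison_report(summaries, alpha: float = ALPHA,
                            large_d: float = LARGE_D) -> StatsReport:
    """Run the three statistics over pooled per-clade Ka/Ks ratio lists."""
    summaries = [s for s in summaries if s.count > 0]
    if len(summaries) < 2:
        raise ValueError("need at least 2 non-empty clades")
    groups = {s.clade: list(s.values) for s in summaries}
    labels = list(groups)
    h, df, p = kruskal_wallis(list(groups.values()))
    adj, letters = pairwise_wilcoxon_holm(groups, alpha)
    dmat = pd.DataFrame(np.zeros((len(labels), len(labels))),
                        index=labels, columns=labels)
    large = []
    for a, b in itertools.combinations(labels, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            d = float("nan")
        else:
            d = cohens_d(groups[a], groups[b])
        dmat.loc[a, b] = dmat.loc[b, a] = d
        if not math.isnan(d) and d > large_d:
            large.append((a, b))
    return StatsReport(
        kw_statistic=h, kw_df=df, kw_p=p, adjusted_p=adj, effect_sizes=dmat,
        letters=letters, large_pairs=large,
        group_sizes={k: len(v) for k, v in groups.items()},
    )
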