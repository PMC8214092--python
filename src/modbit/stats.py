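"""Nonparametric comparison of per-run summaries.

The battery applied to minimum-validation-loss and epochs-to-minimum
samples: a Kruskal-Wallis omnibus (tie-corrected H, chi-squared reference
with k-1 df), the Conover-Iman rank post hoc with Holm's step-down
correction over all unordered pairs, and the two-sided Mann-Whitney U for
two-group conditions.

Kruskal-Wallis and Mann-Whitney delegate to scipy.stats; the Conover-Iman
statistic and Holm's procedure are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.stats as sps

__all__ = ["GroupSamples", "StatReport", "kruskal_wallis", "conover_posthoc",
           "holm_adjust", "mann_whitney", "compare_groups"]

GroupSamples = dict[str, "np.ndarray | list[float]"]


def _clean_groups(groups: GroupSamples) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = arr
    return out


def kruskal_wallis(groups: GroupSamples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    g = _clean_groups(groups)
    if sum(len(v) for v in g.values()) < 3:
        raise ValueError("need at least 3 observations in total")
    H, p = sps.kruskal(*g.values())
    return float(H), float(p)


def conover_posthoc(groups: GroupSamples) -> dict[tuple[str, str], dict[str, float]]:
    """Conover-Iman pairwise rank comparisons after a Kruskal-Wallis omnibus.

    For groups of sizes ``n_i`` with pooled mean ranks ``Rbar_i`` over
    ``N`` observations in ``k`` groups, the statistic for pair (i, j) is

        t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))

    with ``S^2 = (sum r^2 - N (N+1)^2 / 4) / (N - 1)`` computed on the tied
    ranks and ``H`` the tie-corrected Kruskal-Wallis statistic; two-sided
    p-values come from Student's t with ``N - k`` degrees of freedom.

    Returns a mapping from unordered name pairs to
    ``{"statistic", "p", "direction"}`` where ``direction`` is the name of
    the group with the smaller mean rank (None on an exact tie).
    """
    g = _clean_groups(groups)
    names = list(g)
    k = len(names)
    pooled = np.concatenate([g[n] for n in names])
    N = len(pooled)
    if N - k <= 0:
        raise ValueError("need more observations than groups")
    ranks = sps.rankdata(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for n in names:
        m = len(g[n])
        mean_rank[n] = float(np.mean(ranks[start:start + m]))
        sizes[n] = m
        start += m
    H, _ = kruskal_wallis(groups) if k > 1 else (0.0, 1.0)
    s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    factor = max(s2 * (N - 1 - H) / (N - k), 0.0)
    df = N - k
    table = {}
    for a, b in combinations(names, 2):
        denom = np.sqrt(factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        diff = mean_rank[a] - mean_rank[b]
        if denom == 0.0:
            t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        else:
            t = diff / denom
        p = float(2.0 * sps.t.sf(abs(t), df))
        if diff == 0.0:
            direction = None
        else:
            direction = a if diff < 0 else b
        table[(a, b)] = {"statistic": float(t), "p": min(p, 1.0),
                         "direction": direction}
    return table


def holm_adjust(pvals) -> np.ndarray:
    """Holm's step-down adjustment, returned in the input order.

    The i-th smallest p is multiplied by ``m - i + 1``, a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, p[idx] * (m - i))
        adj[idx] = min(running, 1.0)
    return adj


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(min(U_a, U_b), p)``.

    Uses exact enumeration when both samples have at most 8 observations
    and no ties are present, otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_b = len(a) * len(b) - u_a
    return min(u_a, u_b), float(res.pvalue)


@dataclass
class StatReport:
    """Omnibus + post hoc results for one metric across model variants."""

    omnibus_statistic: float
    omnibus_p: float
    pairwise: dict[tuple[str, str], dict[str, float]]

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.pairwise)

    def significant(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [pair for pair, row in self.pairwise.items()
                if row["p_holm"] < alpha]


def compare_groups(groups: GroupSamples) -> StatReport:
    """Kruskal-Wallis omnibus plus Holm-corrected Conover post hoc table."""
    H, p = kruskal_wallis(groups)
    raw = conover_posthoc(groups)
    adj = holm_adjust([row["p"] for row in raw.values()])
    pairwise = {}
    for (pair, row), p_holm in zip(raw.items(), adj):
        pairwise[pair] = dict(row, p_holm=float(p_holm))
    return StatReport(H, p, pairwise)
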