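"""Exact nonparametric tests for small single-molecule samples.

Two tests are implemented from first principles because their *exact*
(permutation) forms are what small-n single-molecule comparisons call for:

* :func:`mannwhitney_exact` — Mann–Whitney U with the exact p-value by
  full enumeration of group assignments (ties handled by enumerating over
  the observed tie pattern) for combined n up to ``exact_max_n``, and the
  tie-corrected normal approximation with continuity correction beyond.
* :func:`kruskal_dunn` — Kruskal–Wallis H with tie correction (exact
  permutation p when the arrangement count is small, chi-square otherwise)
  followed by Dunn's pairwise rank comparisons with multiplicity
  adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._errors import InputError, StatisticsError

__all__ = ["MannWhitneyResult", "KruskalDunnResult", "mannwhitney_exact", "kruskal_dunn"]

_EPS = 1e-12


@dataclass
class MannWhitneyResult:
    statistic: float  # U for the first sample
    pvalue: float
    alternative: str
    method: str  # "exact" or "normal"
    n1: int
    n2: int

    def summary(self) -> str:
        return (
            f"Mann-Whitney U test ({self.method}, {self.alternative})\n"
            f"n1 = {self.n1}, n2 = {self.n2}\n"
            f"U = {self.statistic:g}, p = {self.pvalue:.6g}"
        )


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mannwhitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> MannWhitneyResult:
    """Mann–Whitney U test; exact by enumeration for combined n <= ``exact_max_n``.

    ``alternative='greater'`` tests whether ``x`` tends to exceed ``y``.
    The exact p enumerates all C(n1+n2, n1) assignments of the pooled
    (mid-ranked) observations to the first group, which conditions on the
    observed tie pattern. Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        u_all = np.array(
            [
                _u_from_ranks(sum(ranks[i] for i in combo), n1)
                for combo in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        if alternative == "greater":
            p = np.mean(u_all >= u_obs - _EPS)
        elif alternative == "less":
            p = np.mean(u_all <= u_obs + _EPS)
        else:
            p = np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - _EPS)
        return MannWhitneyResult(float(u_obs), float(p), alternative, "exact", n1, n2)

    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(max(sigma2, _EPS))
    if alternative == "greater":
        p = sps.norm.sf((u_obs - mu - 0.5) / sigma)
    elif alternative == "less":
        p = sps.norm.cdf((u_obs - mu + 0.5) / sigma)
    else:
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(float(u_obs), float(p), alternative, "normal", n1, n2)


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# --------------------------------------------------------------------------

@dataclass
class KruskalDunnResult:
    statistic: float  # tie-corrected H
    pvalue: float
    method: str  # "exact" or "chi2"
    comparisons: pd.DataFrame  # pairwise Dunn z, p, adjusted p
    group_labels: tuple
    group_sizes: tuple

    def summary(self) -> str:
        lines = [
            f"Kruskal-Wallis H = {self.statistic:.4f}, p = {self.pvalue:.6g} "
            f"({self.method})",
            f"groups: {dict(zip(self.group_labels, self.group_sizes))}",
            "Dunn pairwise comparisons:",
            self.comparisons.to_string(index=False),
        ]
        return "\n".join(lines)


def _kw_h(ranks_by_group: Iterable[np.ndarray], n: int, tie_correction: float) -> float:
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in ranks_by_group
    ) - 3.0 * (n + 1)
    # tie_correction == 0 only when every pooled value is identical: H is 0
    return h / tie_correction if tie_correction > 0 else 0.0


def _assignments(indices: tuple, sizes: Sequence[int]):
    if len(sizes) == 1:
        yield (indices,)
        return
    for combo in itertools.combinations(indices, sizes[0]):
        chosen = set(combo)
        rest = tuple(i for i in indices if i not in chosen)
        for tail in _assignments(rest, sizes[1:]):
            yield (combo,) + tail


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    p_adjust: str = "holm",
    exact_limit: int = 20000,
) -> KruskalDunnResult:
    """Kruskal–Wallis ANOVA with Dunn's post-hoc pairwise comparisons.

    The global p-value is exact (full enumeration of group assignments)
    whenever the number of distinct arrangements does not exceed
    ``exact_limit``; otherwise the chi-square approximation is used.
    Dunn z statistics use the pooled-rank variance with tie correction;
    pairwise p-values are two-tailed and adjusted by ``p_adjust``
    (any method accepted by statsmodels ``multipletests``).
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 3:
        raise StatisticsError(
            "kruskal_dunn needs >= 3 groups; for two groups use the exact "
            "Mann-Whitney test (mannwhitney_exact)"
        )
    if any(a.size < 2 for a in arrs):
        raise StatisticsError("every group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    sizes = [a.size for a in arrs]
    n = int(sum(sizes))
    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    tie_correction = 1.0 - tie_sum / (n**3 - n)

    bounds = np.cumsum([0] + sizes)
    ranks_by_group = [ranks[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    h_obs = _kw_h(ranks_by_group, n, tie_correction)

    n_arr = math.factorial(n)
    for s in sizes:
        n_arr //= math.factorial(s)
    if n_arr <= exact_limit:
        count_ge = 0
        for assignment in _assignments(tuple(range(n)), sizes):
            parts = [ranks[np.array(ix)] for ix in assignment]
            if _kw_h(parts, n, tie_correction) >= h_obs - _EPS:
                count_ge += 1
        pvalue, method = count_ge / n_arr, "exact"
    else:
        pvalue, method = float(sps.chi2.sf(h_obs, len(arrs) - 1)), "chi2"

    # Dunn pairwise z statistics
    mean_ranks = [r.mean() for r in ranks_by_group]
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = math.sqrt(max(var_term, 0.0) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "z": z,
             "p_unadjusted": 2.0 * sps.norm.sf(abs(z))}
        )
    comp = pd.DataFrame(rows)
    comp["p_adjusted"] = multipletests(comp["p_unadjusted"], method=p_adjust)[1]
    return KruskalDunnResult(
        float(h_obs), float(pvalue), method, comp, tuple(labels), tuple(sizes)
    )
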