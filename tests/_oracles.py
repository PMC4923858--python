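"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities with naive enumeration so the
package implementations are checked against a different code path.
"""

from __future__ import annotations

import itertools

import numpy as np


def _cumsums(y):
    y = np.asarray(y, dtype=float)
    return np.concatenate(([0.0], np.cumsum(y))), np.concatenate(
        ([0.0], np.cumsum(y * y))
    )


def brute_force_steps(y, penalty, min_size=2, kmax=2):
    """Exhaustive minimum-RSS segmentation for 0..kmax change points.

    Returns (k_selected, {k: best_rss}, {k: best change points}), where k
    is selected by minimizing RSS + penalty * k (first k on ties).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cs, cs2 = _cumsums(y)

    def cost(i, j):
        m = j - i
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        return max(s2 - s * s / m, 0.0)

    def cost_vec(i_arr, j_arr):
        m = j_arr - i_arr
        s = cs[j_arr] - cs[i_arr]
        s2 = cs2[j_arr] - cs2[i_arr]
        return np.maximum(s2 - s * s / m, 0.0)

    rss = {0: cost(0, n)}
    cps = {0: ()}

    if kmax >= 1:
        c1 = np.arange(min_size, n - min_size + 1)
        if c1.size:
            tot = cost_vec(np.zeros_like(c1), c1) + cost_vec(c1, np.full_like(c1, n))
            i = int(np.argmin(tot))
            rss[1], cps[1] = float(tot[i]), (int(c1[i]),)

    if kmax >= 2:
        best = np.inf
        best_cps = None
        tail = {j: cost(j, n) for j in range(min_size, n)}
        for a in range(min_size, n - 2 * min_size + 1):
            head = cost(0, a)
            b = np.arange(a + min_size, n - min_size + 1)
            if not b.size:
                continue
            tot = head + cost_vec(np.full_like(b, a), b) + np.array(
                [tail[int(j)] for j in b]
            )
            i = int(np.argmin(tot))
            if tot[i] < best:
                best, best_cps = float(tot[i]), (a, int(b[i]))
        if best_cps is not None:
            rss[2], cps[2] = best, best_cps

    ks = sorted(rss)
    scores = [rss[k] + penalty * k for k in ks]
    k_sel = ks[int(np.argmin(scores))]
    return k_sel, rss, cps


def permutation_mannwhitney(x, y, alternative):
    """Exact one/two-sided Mann-Whitney p by enumerating ALL orderings.

    O((n1+n2)!) — tiny samples only. Ties handled naturally because U is
    computed from pairwise comparisons on the raw values.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(vals_x, vals_y):
        u = 0.0
        for a in vals_x:
            for b in vals_y:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2.0
    count = 0
    total = 0
    for perm in itertools.permutations(pooled):
        total += 1
        u = u_stat(perm[:n1], perm[n1:])
        if alternative == "greater":
            count += u >= u_obs - 1e-12
        elif alternative == "less":
            count += u <= u_obs + 1e-12
        else:
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return count / total


def permutation_kruskal_h(groups):
    """Exact Kruskal-Wallis permutation p over all n! orderings (vectorized).

    Independent of the package: ranks and H recomputed here, and the
    enumeration runs over full permutations rather than set partitions.
    """
    from scipy.stats import rankdata

    arrs = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrs]
    n = sum(sizes)
    pooled = np.concatenate(arrs)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)

    def h_of(rank_matrix):
        # rank_matrix: (m, n) rank rows; group blocks by sizes
        h = np.zeros(rank_matrix.shape[0])
        start = 0
        for s in sizes:
            block = rank_matrix[:, start: start + s]
            h += block.sum(axis=1) ** 2 / s
            start += s
        h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
        return h / tie_corr if tie_corr > 0 else np.zeros_like(h)

    perms = np.array(list(itertools.permutations(range(n))))
    h_all = h_of(ranks[perms])
    h_obs = h_of(ranks[None, :])[0]
    return float(np.mean(h_all >= h_obs - 1e-12)), float(h_obs)


def binomial_interval(n, p, level=0.99):
    """Central interval of Binomial(n, p) by direct quantiles."""
    from scipy.stats import binom

    alpha = 1 - level
    return binom.ppf(alpha / 2, n, p), binom.ppf(1 - alpha / 2, n, p)
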