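"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's computational paths: brute-force
per-observation likelihood sums, textbook rank-statistic formulas, and
exhaustive enumeration of permutation nulls on tiny inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def brute_mixing_loglik(r, sources, il, tracers):
    """Per-observation normal-density sum for the two-source mixing model."""
    eel, epi = sources
    total = 0.0
    for _, row in il.iterrows():
        for t in tracers:
            m = (1 - r) * eel.means[t] + r * epi.means[t]
            v = (1 - r) ** 2 * eel.sds[t] ** 2 + r**2 * epi.sds[t] ** 2
            if v == 0:
                if row[t] != m:
                    return -math.inf
                continue
            total += sps.norm.logpdf(row[t], loc=m, scale=math.sqrt(v))
    return total


def kruskal_statistic_reference(groups):
    """Tie-corrected Kruskal-Wallis H from the textbook rank-sum formula."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def _pair_stat(a, b):
    """DSCF pair statistic written independently from the package version."""
    m_a, m_b = len(a), len(b)
    m = m_a + m_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = ranks[m_a:].sum()
    e_w = m_b * (m + 1) / 2
    var_w = m_a * m_b / (m * (m - 1)) * ((ranks**2).sum() - m * (m + 1) ** 2 / 4)
    return 0.0 if var_w <= 0 else abs(w - e_w) / math.sqrt(var_w)


def dscf_exact_pvalues(groups):
    """Exhaustive max-statistic permutation p-values for tiny groups.

    Enumerates every distinct partition of the pooled sample into groups of
    the observed sizes; p for each pair is the fraction of partitions whose
    maximum pairwise statistic reaches the observed pair statistic.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    k = len(groups)
    obs = []
    for i in range(k):
        for j in range(i + 1, k):
            obs.append(_pair_stat(groups[i], groups[j]))
    obs = np.array(obs)

    max_stats = []
    all_idx = frozenset(range(n))

    def recurse(remaining, chosen):
        depth = len(chosen)
        if depth == k:
            parts = [pooled[list(c)] for c in chosen]
            stats = []
            for i in range(k):
                for j in range(i + 1, k):
                    stats.append(_pair_stat(parts[i], parts[j]))
            max_stats.append(max(stats))
            return
        for combo in itertools.combinations(sorted(remaining), sizes[depth]):
            recurse(remaining - set(combo), chosen + [combo])

    recurse(set(all_idx), [])
    max_stats = np.array(max_stats)
    return np.array([(max_stats >= o - 1e-12).mean() for o in obs])


def mc_standard_error(draws):
    """Monte-Carlo SE of a chain mean: sd * sqrt(1/ESS) via arviz."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    ess = float(az.ess(draws[None, :]))
    ess = max(min(ess, draws.size), 2.0)
    return draws.std(ddof=1) / math.sqrt(ess)


def effective_sample_size(draws):
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    return max(min(float(az.ess(draws[None, :])), draws.size), 2.0)


def sd_standard_error(draws, variance, excess_kurtosis):
    """MC standard error of a sample SD against an exact target.

    Var(s^2) = (m4 - v^2)/ESS with m4 = v^2(kurt_excess + 3) taken from the
    exact target (empirical fourth moments chronically under-sample heavy
    tails), and ESS measured on the centered-squares chain, which carries the
    autocorrelation that an SD estimate actually feels; delta method then
    gives Var(s) ~ Var(s^2)/(4v).
    """
    draws = np.asarray(draws, dtype=float)
    z = (draws - draws.mean()) ** 2
    n_eff = effective_sample_size(z)
    m4 = variance**2 * (excess_kurtosis + 3.0)
    return math.sqrt((m4 - variance**2) / (4.0 * variance * n_eff))


def ig_excess_kurtosis(shape):
    """Excess kurtosis of an inverse-gamma distribution (finite for shape>4)."""
    if shape <= 4:
        return math.inf
    return (30 * shape - 66.0) / ((shape - 3.0) * (shape - 4.0))


def t_excess_kurtosis(df):
    """Excess kurtosis of a Student-t distribution (finite for df>4)."""
    if df <= 4:
        return math.inf
    return 6.0 / (df - 4.0)


def mc_standard_error_sd(draws):
    """Monte-Carlo SE of a chain SD estimate (delta method, 4th moment).

    Var(s) ~ (m4 - s^4) / (4 s^2 n_eff); matters for heavy-tailed draws such
    as inverse-gamma variance chains, where sd/sqrt(2n) badly understates it.
    """
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    ess = float(az.ess(draws[None, :]))
    ess = max(min(ess, draws.size), 2.0)
    s2 = draws.var(ddof=1)
    m4 = ((draws - draws.mean()) ** 4).mean()
    return math.sqrt(max(m4 - s2**2, 0.0) / (4 * s2 * ess))
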