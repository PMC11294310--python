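"""Independent brute-force oracles used to cross-check the statistics."""

import itertools

import numpy as np
from scipy import stats


def exact_wilcoxon_by_enumeration(x, y):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [np.sum(ranks[list(signs)]) for signs in
         (np.array(bits, bool) for bits in itertools.product([0, 1], repeat=n))]
    )
    lower = np.mean(w_all <= w_obs + 1e-12)
    upper = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def alpha_by_pair_enumeration(values):
    """Ordinal Krippendorff alpha from explicit pair lists (no matrix).

    Observed disagreement averages the ordinal squared distance over all
    ordered within-unit pairs (weight 1/(m_u - 1)); expected disagreement
    averages it over all ordered pairs of pairable values.
    """
    values = np.asarray(values, float)
    units = [row[~np.isnan(row)] for row in values]
    units = [u for u in units if u.size >= 2]
    pairable = np.concatenate(units)
    cats = np.unique(pairable)
    # marginal counts enter the ordinal metric
    n_g = {c: np.sum(pairable == c) for c in cats}

    def dist2(a, b):
        lo, hi = min(a, b), max(a, b)
        span = sum(n_g[c] for c in cats if lo <= c <= hi)
        return (span - (n_g[a] + n_g[b]) / 2.0) ** 2

    num = den = 0.0
    for u in units:
        m = u.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    num += dist2(u[i], u[j]) / (m - 1)
    n_tot = pairable.size
    for a in pairable:
        for b in pairable:
            den += dist2(a, b)
    d_obs = num / n_tot
    d_exp = den / (n_tot * (n_tot - 1))
    if d_exp == 0:
        return float("nan")
    return 1.0 - d_obs / d_exp
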