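"""Independently coded brute-force oracles.

Deliberately naive: plain-Python loops straight from the defining
formulas, sharing no code with the package implementation they check.
"""

import math


def naive_cohens_d(n_t, mean_t, sd_t, n_c, mean_c, sd_c, lower_is_better=True):
    diff = (mean_c - mean_t) if lower_is_better else (mean_t - mean_c)
    pooled = math.sqrt(
        ((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / (n_t + n_c - 2))
    d = diff / pooled
    var = (n_t + n_c) / (n_t * n_c) + d * d / (2 * (n_t + n_c))
    return d, var


def naive_pool_fixed(ds, vs):
    num = 0.0
    den = 0.0
    for d, v in zip(ds, vs):
        num += d / v
        den += 1.0 / v
    return num / den, math.sqrt(1.0 / den)


def naive_pool_dl(ds, vs):
    k = len(ds)
    ws = [1.0 / v for v in vs]
    sw = sum(ws)
    d_fixed = sum(w * d for w, d in zip(ws, ds)) / sw
    q = sum(w * (d - d_fixed) ** 2 for w, d in zip(ws, ds))
    denom = sw - sum(w * w for w in ws) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    ws2 = [1.0 / (v + tau2) for v in vs]
    sw2 = sum(ws2)
    d_pooled = sum(w * d for w, d in zip(ws2, ds)) / sw2
    return d_pooled, tau2, math.sqrt(1.0 / sw2)


def naive_kappa(a, b, weight=None):
    """Kappa from two equal-length score lists via explicit confusion counts.

    weight: None (unweighted), 'linear' or 'quadratic'.
    """
    n = len(a)
    cats = (0, 1, 2)
    conf = {(i, j): 0 for i in cats for j in cats}
    for x, y in zip(a, b):
        conf[(x, y)] += 1
    row = {i: sum(conf[(i, j)] for j in cats) / n for i in cats}
    col = {j: sum(conf[(i, j)] for i in cats) / n for j in cats}

    def w(i, j):
        if weight is None:
            return 0.0 if i == j else 1.0
        if weight == "linear":
            return abs(i - j) / 2.0
        return ((i - j) / 2.0) ** 2

    obs = sum(w(i, j) * conf[(i, j)] / n for i in cats for j in cats)
    exp = sum(w(i, j) * row[i] * col[j] for i in cats for j in cats)
    return 1.0 - obs / exp


def naive_welch_p(n_t, mean_t, sd_t, n_c, mean_c, sd_c):
    """Two-sided Welch t-test p via the t survival function (scipy dist only)."""
    from scipy.stats import t as t_dist

    se2_t = sd_t**2 / n_t
    se2_c = sd_c**2 / n_c
    t_stat = (mean_t - mean_c) / math.sqrt(se2_t + se2_c)
    df = (se2_t + se2_c) ** 2 / (
        se2_t**2 / (n_t - 1) + se2_c**2 / (n_c - 1))
    return 2.0 * t_dist.sf(abs(t_stat), df)
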