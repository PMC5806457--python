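"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the package's own code paths: alpha is computed by
direct enumeration of all within-unit and cross-unit value pairs, never via
a coincidence matrix.
"""

import numpy as np


def ratio_delta_sq(c, k):
    if c == k == 0:
        return 0.0
    return ((c - k) / (c + k)) ** 2


def brute_force_alpha(ratings):
    """Ratio-scale Krippendorff alpha by exhaustive pair enumeration.

    D_o: average disagreement over all ordered within-unit pairs, each unit
    weighted by 1/(m_u - 1).  D_e: average disagreement over all ordered
    pairs of the pooled pairable values.
    """
    arr = np.asarray(getattr(ratings, "values", ratings), dtype=float)
    units = [row[~np.isnan(row)] for row in arr]
    units = [u for u in units if len(u) >= 2]
    pooled = np.concatenate(units)
    n = len(pooled)

    d_obs = 0.0
    for u in units:
        m = len(u)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += ratio_delta_sq(u[i], u[j]) / (m - 1)
    d_obs /= n

    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += ratio_delta_sq(pooled[i], pooled[j])
    d_exp /= n * (n - 1)

    if d_obs == 0.0 or d_exp == 0.0:
        return 1.0
    return 1.0 - d_obs / d_exp


def random_ratings(rng, max_units=6, max_raters=3, max_count=5):
    """A random small ratings matrix guaranteed to be alpha-computable."""
    while True:
        n_units = rng.integers(2, max_units + 1)
        n_raters = rng.integers(2, max_raters + 1)
        mat = rng.integers(0, max_count + 1, size=(n_units, n_raters)).astype(float)
        mask = rng.random((n_units, n_raters)) < 0.2
        mat[mask] = np.nan
        pairable = (~np.isnan(mat)).sum(axis=1) >= 2
        if pairable.sum() >= 2:
            return mat
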