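"""Independent brute-force oracles, deliberately naive.

These re-derive the quantities the package computes via a different route
(plain double loops, scalar math) so the tests compare two independent
implementations rather than a function against itself.
"""

from __future__ import annotations

import math

import numpy as np

R = 8.314462618e-3  # kJ/mol/K


def naive_bias_factor(edge_lo: float, edge_hi: float, center: float, k: float,
                      rt: float) -> float:
    """Bin-averaged exp(-U/RT) for a harmonic bias, scalar erf arithmetic."""
    if k == 0.0:
        return 1.0
    a = math.sqrt(0.5 * k / rt)
    width = edge_hi - edge_lo
    return (
        math.sqrt(math.pi)
        / 2.0
        * (math.erf(a * (edge_hi - center)) - math.erf(a * (edge_lo - center)))
        / (a * width)
    )


def naive_wham(edges, counts, centers, force_constants, temperature,
               tol=1e-12, max_iter=2_000_000):
    """Direct WHAM fixed-point iteration as an explicit double loop.

    Returns (bin_centers, g, f) with g = -RT ln P (NaN on empty bins) and P
    normalised over occupied bins.  Intended only for tiny instances.
    """
    edges = list(map(float, edges))
    n_bins = len(edges) - 1
    n_win = len(centers)
    rt = R * temperature
    zb = [(edges[b] + edges[b + 1]) / 2.0 for b in range(n_bins)]
    c = [
        [
            naive_bias_factor(edges[b], edges[b + 1], centers[i],
                              force_constants[i], rt)
            for b in range(n_bins)
        ]
        for i in range(n_win)
    ]
    pooled = [sum(counts[i][b] for i in range(n_win)) for b in range(n_bins)]
    n_tot = [sum(counts[i][b] for b in range(n_bins)) for i in range(n_win)]
    f = [0.0] * n_win
    for _ in range(max_iter):
        p = []
        for b in range(n_bins):
            denom = 0.0
            for i in range(n_win):
                denom += n_tot[i] * math.exp(f[i] / rt) * c[i][b]
            p.append(pooled[b] / denom if (pooled[b] > 0 and denom > 0) else 0.0)
        s = sum(p)
        p = [x / s for x in p]
        f_new = []
        for i in range(n_win):
            zsum = sum(c[i][b] * p[b] for b in range(n_bins))
            f_new.append(-rt * math.log(zsum))
        resid = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if resid < tol:
            break
    g = [(-rt * math.log(x)) if x > 0 else float("nan") for x in p]
    return np.array(zb), np.array(g), np.array(f)


def grid_minimum(func, lo, hi, n=200_001):
    """Brute-force minimiser of a callable on a dense grid."""
    z = np.linspace(lo, hi, n)
    v = func(z)
    i = int(np.argmin(v))
    return float(z[i]), float(v[i])
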