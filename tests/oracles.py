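"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive nested loops / exact plug-in formulas and share
no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Naive O(N^2) sample entropy: explicit template loops, Chebyshev
    distance, self-matches excluded, each unordered pair counted once."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    n_templates = n - m
    b = a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            dist_m = max(abs(x[i + t] - x[j + t]) for t in range(m))
            if dist_m <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    cap = math.log((n - m) * (n - m - 1)) - math.log(2.0)
    if b == 0 or a == 0:
        return cap
    return -math.log(a / b)


def hurst_bruteforce(x, min_lag: int = 2, max_lag: int = 20) -> float:
    """Naive block-averaged rescaled-range slope estimate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    log_tau, log_rs = [], []
    for tau in range(min_lag, max_lag + 1):
        ratios = []
        for b in range(n // tau):
            block = x[b * tau:(b + 1) * tau]
            mean = sum(block) / tau
            dev = np.cumsum([v - mean for v in block])
            r = max(dev) - min(dev)
            s = math.sqrt(sum((v - mean) ** 2 for v in block) / tau)
            if s > 0:
                ratios.append(r / s)
        if ratios:
            rs = sum(ratios) / len(ratios)
            if rs > 0:
                log_tau.append(math.log(tau))
                log_rs.append(math.log(rs))
    if len(log_tau) < 2:
        return 0.5
    slope = np.polyfit(log_tau, log_rs, 1)[0]
    return float(min(max(slope, 0.0), 1.5))


def plugin_mi(x, y) -> float:
    """Exact discrete plug-in mutual information (nats) from the empirical
    joint probability table: I = sum p(x,y) log[p(x,y)/(p(x)p(y))]."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        px = np.mean(x == xv)
        for yv in np.unique(y):
            py = np.mean(y == yv)
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    return mi
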