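"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately naive: exhaustive enumeration or direct
closed forms, sharing no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb, floor

import numpy as np


def _rankdata(vals):
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_two_sided_exact(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = _rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    us = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        r = sum(ranks[i] for i in idx)
        us.append(r - n1 * (n1 + 1) / 2.0)
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by summing the hypergeometric tail directly."""
    row1, col1, n = a + b, a + c, a + b + c + d
    total = comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += comb(row1, k) * comb(n - row1, col1 - k) / total
    return p


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho and exact two-sided permutation p (no ties, small n)."""
    n = len(x)
    rx = _rankdata(list(x))
    ry = _rankdata(list(y))
    def rho_of(r2):
        d2 = sum((a - b) ** 2 for a, b in zip(rx, r2))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    rho = rho_of(ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(perm)) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def ks_one_sided_exact(data, cdf) -> tuple[float, float]:
    """One-sided (D+) KS statistic and exact Birnbaum-Tingey p-value.

    Tests the alternative that the data are stochastically smaller than
    the reference distribution (empirical CDF above the reference CDF).
    """
    xs = sorted(data)
    n = len(xs)
    d_plus = max((i + 1) / n - cdf(x) for i, x in enumerate(xs))
    if d_plus <= 0.0:
        return max(d_plus, 0.0), 1.0
    if d_plus >= 1.0:
        return d_plus, 0.0
    # P(D+ >= d) = d * sum_{j=0}^{floor(n(1-d))} C(n,j)(j/n+d)^{j-1}(1-d-j/n)^{n-j}
    total = 0.0
    for j in range(floor(n * (1.0 - d_plus)) + 1):
        term = comb(n, j)
        term *= (j / n + d_plus) ** (j - 1)
        term *= (1.0 - d_plus - j / n) ** (n - j)
        total += term
    p = d_plus * total
    return d_plus, float(min(1.0, max(0.0, p)))


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out
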