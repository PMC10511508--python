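"""Independent brute-force oracles used to pin down expected values.

These deliberately use plain Python loops and a different formulation path
than the package (which vectorizes over splits with shared pooled tables).
"""

from __future__ import annotations

import numpy as np


def ad_midrank_oracle(left, right) -> float:
    """Tie-adjusted two-sample AD statistic by direct enumeration.

    Loops over the distinct pooled values, accumulating midrank cumulative
    counts term by term (Scholz-Stephens discrete form for k = 2).
    """
    left, right = list(left), list(right)
    n, m = len(left), len(right)
    N = n + m
    pooled = sorted(left + right)
    distinct = sorted(set(pooled))
    total = 0.0
    cum = {0: 0.0, 1: 0.0}
    cum_pool = 0.0
    for val in distinct:
        l_j = pooled.count(val)
        f = {0: left.count(val), 1: right.count(val)}
        B = cum_pool + l_j / 2.0
        denom = B * (N - B) - N * l_j / 4.0
        if denom > 1e-12:
            for i, sample_n in ((0, n), (1, m)):
                M = cum[i] + f[i] / 2.0
                total += (l_j / N) * (N * M - sample_n * B) ** 2 / denom / sample_n
        cum[0] += f[0]
        cum[1] += f[1]
        cum_pool += l_j
    return (N - 1) / N * total


def ad_continuous_oracle(left, right) -> float:
    """Discrete AD sum for continuous (untied) data over pooled order stats.

    A2 = (1/(n*m)) * sum_{j=1}^{N-1} (N*M_j - j*n)^2 / (j*(N-j)), with M_j the
    number of left-side observations among the j smallest pooled values.
    """
    left, right = list(left), list(right)
    n, m = len(left), len(right)
    N = n + m
    order = sorted(range(N), key=lambda i: (left + right)[i])
    total = 0.0
    M = 0
    for j in range(1, N):
        if order[j - 1] < n:
            M += 1
        total += (N * M - j * n) ** 2 / (j * (N - j))
    return total / (n * m)


def trimmed_mean_oracle(values, trim: float) -> float:
    """Sort, drop floor(trim*n) from each end, average."""
    v = sorted(values)
    k = int(np.floor(trim * len(v)))
    kept = v[k : len(v) - k] if len(v) - 2 * k > 0 else v
    return sum(kept) / len(kept)
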