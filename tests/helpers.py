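"""Independent oracles used by the tests.

These deliberately re-derive results from first principles (naive loops,
unpruned dynamic programming, exhaustive search) so they share no code with
the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_segment_cost(y, start, stop, sigma2, mbic=False):
    """Two-pass mean-change cost of y[start:stop]."""
    seg = list(y[start:stop])
    mean = sum(seg) / len(seg)
    sse = sum((v - mean) ** 2 for v in seg)
    cost = sse / sigma2
    if mbic:
        cost += math.log(len(seg))
    return cost


def dp_segmentation(y, penalty, sigma2, min_segment_length=2):
    """O(n^2) unpruned optimal segmentation; ties to smaller split index."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    mbic = penalty == "MBIC"
    beta = (2.0 if penalty == "SIC" else 3.0) * math.log(n)
    F = [math.inf] * (n + 1)
    F[0] = -beta
    prev = [0] * (n + 1)
    for t in range(min_segment_length, n + 1):
        starts = [0] + [
            s for s in range(min_segment_length, t - min_segment_length + 1)
        ]
        best = None
        arg = None
        for s in starts:
            if not math.isfinite(F[s]):
                continue
            v = F[s] + naive_segment_cost(y, s, t, sigma2, mbic) + beta
            if best is None or v < best - 1e-12:
                best, arg = v, s
        F[t] = best
        prev[t] = arg
    bps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def amoc_exhaustive(y, penalty, sigma2, min_segment_length=2):
    """Exhaustive single-split search with penalised comparison."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    mbic = penalty == "MBIC"
    beta = (2.0 if penalty == "SIC" else 3.0) * math.log(n)
    best = None
    arg = None
    for tau in range(min_segment_length, n - min_segment_length + 1):
        v = naive_segment_cost(y, 0, tau, sigma2, mbic) + naive_segment_cost(
            y, tau, n, sigma2, mbic
        )
        if best is None or v < best - 1e-12:
            best, arg = v, tau
    if best is not None and best + beta < naive_segment_cost(y, 0, n, sigma2, mbic):
        return [arg]
    return []


def random_changepoint_vector(rng, max_n=50):
    """A random vector, half the time with planted mean shifts."""
    n = int(rng.integers(6, max_n + 1))
    y = rng.normal(size=n)
    if rng.random() < 0.5:
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(2, n - 1))
            y[pos:] += rng.normal() * 3.0
    return y
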