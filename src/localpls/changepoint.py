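"""Change-in-mean detection for ordered distance vectors.

The neighbour-selection rule reads the sorted Mahalanobis distances from a
predictand to every candidate spectrum and asks where the mean of that
vector shifts: the first shift far enough along the vector marks the end of
the "similar" group.  Two detectors are provided:

* AMOC - at most one change, by exhaustive single-split search with a
  penalised likelihood-ratio decision;
* PELT - exact multiple-changepoint optimisation of a penalised Gaussian
  mean-change likelihood, with the standard pruning rule (the per-segment
  cost is non-decreasing under extension, so pruning preserves exactness).

Cost convention: a segment contributes its sum of squares about the segment
mean divided by a common noise variance ``sigma2`` (twice the negative
profile log-likelihood up to constants).  Penalties: SIC ``beta = 2 log n``
(one mean plus one location parameter per changepoint); MBIC
``beta = 3 log n`` with an additive ``log(segment length)`` term per
segment, after Zhang & Siegmund.  ``sigma2`` is by default estimated with
the first-difference estimator ``Var(diff(y))/2``, which is robust to mean
shifts and makes the segmentation invariant to the overall scale of the
distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ChangepointConfig",
    "ChangepointResult",
    "segment_cost",
    "estimate_sigma2",
    "penalty_value",
    "detect_amoc",
    "detect_pelt",
    "detect",
]


@dataclass
class ChangepointConfig:
    method: Literal["AMOC", "PELT"] = "PELT"
    penalty: Literal["SIC", "MBIC"] = "MBIC"
    variance_mode: Literal["difference_estimator", "fixed_one", "global_mle"] = (
        "difference_estimator"
    )
    min_segment_length: int = 2

    def __post_init__(self) -> None:
        if self.min_segment_length < 1:
            raise ValueError("min_segment_length must be >= 1")
        if self.penalty not in ("SIC", "MBIC"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.method not in ("AMOC", "PELT"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ChangepointResult:
    """Detected segmentation of an ordered vector.

    ``changepoints`` holds, for every non-final segment, the 1-based index
    of its last element (equivalently the number of elements up to and
    including the segment end) in increasing order.
    """

    changepoints: list[int] = field(default_factory=list)
    total_cost: float = 0.0
    penalty_value: float = 0.0
    sigma2: float = 1.0

    @property
    def n_segments(self) -> int:
        return len(self.changepoints) + 1


def segment_cost(y: np.ndarray, start: int, stop: int, sigma2: float) -> float:
    """Gaussian mean-change cost of ``y[start:stop]`` (half-open, 0-based).

    ``sum((y_i - mean)^2) / sigma2``; zero for a constant segment.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    seg = np.asarray(y, dtype=float)[start:stop]
    if seg.size == 0:
        raise ValueError("empty segment")
    return float(((seg - seg.mean()) ** 2).sum() / sigma2)


def estimate_sigma2(y: np.ndarray, mode: str = "difference_estimator") -> float:
    """Noise-variance estimate used to scale the mean-change cost.

    ``difference_estimator``: Var(y_{i+1}-y_i)/2, robust to mean shifts.
    ``fixed_one``: 1 (the common known-variance convention).
    ``global_mle``: mean((y - ybar)^2).
    Degenerate (zero) estimates are floored at machine-epsilon scale.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations to estimate sigma2")
    if mode == "fixed_one":
        return 1.0
    if mode == "difference_estimator":
        d = np.diff(y)
        est = float(np.var(d, ddof=1) / 2.0) if d.size > 1 else float(d[0] ** 2 / 2.0)
    elif mode == "global_mle":
        est = float(np.mean((y - y.mean()) ** 2))
    else:
        raise ValueError(f"unknown variance mode {mode!r}")
    floor = np.finfo(float).eps * max(1.0, float(np.mean(y**2)))
    if est < floor:
        warnings.warn(
            f"sigma2 estimate {est:g} is degenerate; flooring at {floor:g}",
            stacklevel=2,
        )
        est = floor
    return est


def penalty_value(penalty: str, n: int) -> float:
    """Per-changepoint penalty: SIC ``2 log n``, MBIC ``3 log n``."""
    if penalty == "SIC":
        return 2.0 * math.log(n)
    if penalty == "MBIC":
        return 3.0 * math.log(n)
    raise ValueError(f"unknown penalty {penalty!r}")


def _prepare(y, cfg):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    sigma2 = estimate_sigma2(y, cfg.variance_mode)
    beta = penalty_value(cfg.penalty, n)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y * y)])
    mbic = cfg.penalty == "MBIC"

    def cost(s, t):
        # Vectorised over s; segment y[s:t], half-open.
        length = t - s
        sse = css[t] - css[s] - (cs[t] - cs[s]) ** 2 / length
        c = sse / sigma2
        if mbic:
            c = c + np.log(length)
        return c

    return y, n, sigma2, beta, cost


def detect_amoc(y: np.ndarray, cfg: ChangepointConfig | None = None) -> ChangepointResult:
    """At-most-one-change detection by exhaustive single-split search.

    The best split is reported only when its penalised cost beats the
    no-change model; ties go to the smaller index.
    """
    cfg = cfg or ChangepointConfig(method="AMOC")
    y, n, sigma2, beta, cost = _prepare(y, cfg)
    m = cfg.min_segment_length
    if n < 2 * m:
        raise ValueError(f"need at least {2 * m} observations for AMOC")
    taus = np.arange(m, n - m + 1)
    split_costs = cost(0, taus) + cost(taus, n)
    k = int(np.argmin(split_costs))  # first minimum -> smallest tau
    no_change = float(cost(0, n))
    if split_costs[k] + beta < no_change:
        return ChangepointResult(
            changepoints=[int(taus[k])],
            total_cost=float(split_costs[k]),
            penalty_value=beta,
            sigma2=sigma2,
        )
    return ChangepointResult(
        changepoints=[], total_cost=no_change, penalty_value=beta, sigma2=sigma2
    )


def detect_pelt(y: np.ndarray, cfg: ChangepointConfig | None = None) -> ChangepointResult:
    """Exact penalised multiple-changepoint detection (PELT).

    Minimises ``sum_j cost(segment_j) + m * beta`` over all segmentations
    respecting ``min_segment_length``.  Pruning never discards a candidate
    that could still be optimal, so the result equals the unpruned dynamic
    programme; dynamic-programme ties are broken toward the smaller
    changepoint index.
    """
    cfg = cfg or ChangepointConfig()
    y, n, sigma2, beta, cost = _prepare(y, cfg)
    m = cfg.min_segment_length
    if n < 2:
        raise ValueError("need at least 2 observations")
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    cand = [0]
    for t in range(m, n + 1):
        tau_new = t - m
        if tau_new > 0 and np.isfinite(F[tau_new]):
            cand.append(tau_new)
        taus = np.array(cand)
        vals = F[taus] + cost(taus, t) + beta
        k = int(np.argmin(vals))  # candidates ascending -> smallest tau wins ties
        F[t] = vals[k]
        prev[t] = taus[k]
        keep = vals - beta <= F[t]
        cand = [int(tau) for tau, ok in zip(taus, keep) if ok]
    bps: list[int] = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bps.append(int(s))
        t = s
    bps.reverse()
    bounds = [0] + bps + [n]
    total = float(sum(cost(s, t) for s, t in zip(bounds, bounds[1:])))
    return ChangepointResult(
        changepoints=bps, total_cost=total, penalty_value=beta, sigma2=sigma2
    )


def detect(y: np.ndarray, cfg: ChangepointConfig) -> ChangepointResult:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "AMOC":
        return detect_amoc(y, cfg)
    return detect_pelt(y, cfg)
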