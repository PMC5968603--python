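"""Weighted summary statistics for survey microdata.

All routines take a vector of observations and a conforming vector of
positive survey weights. The median convention throughout the package is
the *lower weighted median*: the smallest observed value whose cumulative
weight reaches half the total weight. Quantiles generalise the same way.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "weighted_quantile",
    "weighted_median",
    "weighted_mean",
    "weighted_sd",
    "weighted_quintile_labels",
]


def _validate(values, weights):
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-d and of equal length")
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return v, w


def weighted_quantile(values, weights, q: float) -> float:
    """Lower weighted q-quantile: smallest x with cumweight(x) >= q * total."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    v, w = _validate(values, weights)
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, q * cw[-1], side="left"))
    idx = min(idx, v.size - 1)
    return float(v[order][idx])


def weighted_median(values, weights) -> float:
    return weighted_quantile(values, weights, 0.5)


def weighted_mean(values, weights) -> float:
    v, w = _validate(values, weights)
    return float(np.sum(v * w) / np.sum(w))


def weighted_sd(values, weights) -> float:
    """Population-style weighted standard deviation."""
    v, w = _validate(values, weights)
    m = np.sum(v * w) / np.sum(w)
    return float(np.sqrt(np.sum(w * (v - m) ** 2) / np.sum(w)))


def weighted_quintile_labels(values, weights) -> np.ndarray:
    """Assign quintile labels 1..5 by weighted quantile cut points.

    Ties at a cut point fall into the lower quintile, consistent with the
    lower-quantile convention.
    """
    v, w = _validate(values, weights)
    cuts = [weighted_quantile(v, w, q) for q in (0.2, 0.4, 0.6, 0.8)]
    return (np.searchsorted(np.asarray(cuts), v, side="left") + 1).astype(np.int64)
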