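"""Expansion-weighted quantiles with a fixed, library-independent convention.

Survey expansion factors act as frequency weights.  The convention here is
linear interpolation on the normalized cumulative weight: after dividing the
weights by their mean, the sorted value ``x_(i)`` sits at plotting position

    p_i = (W_{i-1}') / (n - 1),   W' = cumulative normalized weight,

which reduces *exactly* to numpy's default ``linear`` quantile method when
all weights are equal, and is invariant to rescaling all weights by a
constant.
"""

from __future__ import annotations

import numpy as np


def weighted_quantile(values, q, weights=None) -> float:
    """Quantile ``q`` of ``values`` with frequency ``weights``.

    Parameters
    ----------
    values : array-like
        Observations.
    q : float
        Quantile level in [0, 1].
    weights : array-like, optional
        Positive frequency weights; defaults to equal weights.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty set")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level must be in [0, 1], got {q}")
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise ValueError("weights must match values in shape")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    if v.size == 1:
        return float(v[0])
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    w = w / w.mean()
    positions = np.concatenate(([0.0], np.cumsum(w)[:-1])) / (v.size - 1)
    return float(np.interp(q, positions, v))


def top_fraction_threshold(values, top_q, weights=None) -> float:
    """Threshold such that values ``>=`` it form (about) the top ``top_q``."""
    return weighted_quantile(values, 1.0 - top_q, weights)
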