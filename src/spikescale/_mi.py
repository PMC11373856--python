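"""Numba kernels for past-state embedding and contingency counting.

Only the O(n) passes over the binned series live here; entropies and the
shuffle-bias correction operate on the (2^d x 2) contingency tables and are
plain numpy (see predictability.py).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _past_codes(a, csum, edges, t0):
    """d-digit binary past codes for t = t0..n-1 (nearest past bin = LSB).

    edges[i]..edges[i+1] are cumulative distances (in bins) back from t;
    bit i is set iff a spike falls in bins [t - edges[i+1], t - edges[i]).
    """
    n = a.shape[0]
    d = edges.shape[0] - 1
    codes = np.empty(n - t0, dtype=np.int64)
    for t in range(t0, n):
        code = 0
        for i in range(d):
            cnt = csum[t - edges[i]] - csum[t - edges[i + 1]]
            if cnt > 0:
                code |= 1 << i
        codes[t - t0] = code
    return codes


@njit(cache=True)
def joint_counts(a, csum, edges):
    """Joint (past code, current bit) counts for one embedding."""
    n = a.shape[0]
    d = edges.shape[0] - 1
    t0 = edges[d]
    joint = np.zeros((1 << d, 2), dtype=np.int64)
    for t in range(t0, n):
        code = 0
        for i in range(d):
            cnt = csum[t - edges[i]] - csum[t - edges[i + 1]]
            if cnt > 0:
                code |= 1 << i
        joint[code, a[t]] += 1
    return joint
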