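"""Independent brute-force oracles, kept free of package internals."""

from itertools import combinations

import numpy as np


def brute_force_structure_map(frame, window, stride):
    """Per-window sample SD by explicit window extraction."""
    frame = np.asarray(frame, dtype=np.float64)
    H, W = frame.shape
    n_rows = (H - window) // stride + 1
    n_cols = (W - window) // stride + 1
    out = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        for j in range(n_cols):
            block = frame[i * stride : i * stride + window,
                          j * stride : j * stride + window]
            out[i, j] = block.std(ddof=1)
    return out


def exact_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank assignments.

    Assumes tie-free pooled data. p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1, where U is the U statistic of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1  # tie-free, so ordinal ranks
    n_a = a.size
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    all_ranks = np.arange(1, pooled.size + 1)
    us = []
    for comb in combinations(all_ranks, n_a):
        us.append(sum(comb) - n_a * (n_a + 1) / 2)
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p), u_obs


def track_speed_by_step_summation(t, x, y, pixel_size):
    """Mean speed re-derived by explicit per-step summation."""
    total = 0.0
    for k in range(1, len(t)):
        total += ((x[k] - x[k - 1]) ** 2 + (y[k] - y[k - 1]) ** 2) ** 0.5
    return total * pixel_size / (t[-1] - t[0])
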