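"""Brute-force oracle for the dip statistic.

The dip of an empirical CDF F_n is min over unimodal distribution functions G
of sup_x |F_n(x) - G(x)|.  A unimodal G is convex on (-inf, m] and concave on
[m, inf) for some mode m (atoms are allowed at the mode).  For a fixed modal
configuration the minimal achievable sup distance is a linear programme in the
values of G at the distinct sample points, because

* F_n is piecewise constant, so the sup is attained at one-sided limits at
  sample points;
* convexity/concavity are linear constraints on slopes between consecutive
  sample points;
* to the left of the smallest point any value g_1 >= 0 with any first-segment
  slope is reachable by a convex hinge decaying to 0, and symmetrically on the
  right, so the tails add only |G| <= t style constraints.

Modes at a data point v_k cover everything: G may carry an atom there (left
limit gm_minus constrained only by F(v_k-), right value gm_plus only by
F(v_k)).  A mode strictly inside a gap (v_k, v_{k+1}) is never needed: for a
mode at position m in the gap the joining constraints are linear in m, so
feasibility at an interior m implies feasibility with the mode pushed to one
of the two adjacent sample points (the atom travelling with it).  The oracle
minimises t over all k with scipy.optimize.linprog; it is exact up to LP
tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_oracle(values) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts) / n  # F_n(v_i)
    c_lo = np.concatenate([[0.0], c[:-1]])  # F_n(v_i-)
    d = v.size
    if d == 1:
        return 0.0
    best = np.inf
    for k in range(d):
        best = min(best, _solve_mode_at_point(v, c, c_lo, k))
    return float(best)


def _solve(v, c, c_lo, n_g, dev_pairs, convex_segs, concave_segs, free_seg=None):
    """Minimise t over G values subject to monotonicity, shape and deviation.

    Variables: g_0..g_{n_g-1}, t.  ``dev_pairs`` is a list of (g index, target)
    with |g - target| <= t.  ``convex_segs`` / ``concave_segs`` are index pairs
    (a, b) of consecutive segments (each segment a pair of g-indices with
    x-coordinates) whose slopes must be nondecreasing / nonincreasing.
    """
    t_idx = n_g
    A_ub, b_ub = [], []

    def row():
        return np.zeros(n_g + 1)

    # 0 <= g <= 1 and monotone nondecreasing handled via bounds + pair rows
    for i in range(n_g - 1):
        r = row()
        r[i], r[i + 1] = 1.0, -1.0  # g_i <= g_{i+1}
        A_ub.append(r)
        b_ub.append(0.0)
    for gi, target in dev_pairs:
        r = row()
        r[gi], r[t_idx] = 1.0, -1.0
        A_ub.append(r)
        b_ub.append(target)  # g - t <= target
        r = row()
        r[gi], r[t_idx] = -1.0, -1.0
        A_ub.append(r)
        b_ub.append(-target)  # -g - t <= -target
    # slope constraints: each entry ((i1, x1, i2, x2), (i3, x3, i4, x4))
    for (i1, x1, i2, x2), (i3, x3, i4, x4) in convex_segs:
        # slope(seg1) <= slope(seg2):
        # (g2-g1)/(x2-x1) - (g4-g3)/(x4-x3) <= 0
        r = row()
        dx1, dx2 = x2 - x1, x4 - x3
        r[i2] += 1.0 / dx1
        r[i1] -= 1.0 / dx1
        r[i4] -= 1.0 / dx2
        r[i3] += 1.0 / dx2
        A_ub.append(r)
        b_ub.append(0.0)
    for (i1, x1, i2, x2), (i3, x3, i4, x4) in concave_segs:
        r = row()
        dx1, dx2 = x2 - x1, x4 - x3
        r[i2] -= 1.0 / dx1
        r[i1] += 1.0 / dx1
        r[i4] += 1.0 / dx2
        r[i3] -= 1.0 / dx2
        A_ub.append(r)
        b_ub.append(0.0)
    cost = np.zeros(n_g + 1)
    cost[t_idx] = 1.0
    bounds = [(0.0, 1.0)] * n_g + [(0.0, None)]
    res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - LP is always feasible
        raise RuntimeError(f"dip oracle LP failed: {res.message}")
    return res.x[-1]


def _segments(idx_x):
    """Consecutive-segment pairs for a list of (g index, x) points."""
    segs = [
        (idx_x[i][0], idx_x[i][1], idx_x[i + 1][0], idx_x[i + 1][1])
        for i in range(len(idx_x) - 1)
    ]
    return list(zip(segs[:-1], segs[1:]))


def _solve_mode_at_point(v, c, c_lo, k):
    d = v.size
    # g variables: one per point except point k gets two (left limit, value)
    idx = {}
    n_g = 0
    for i in range(d):
        if i == k:
            idx[("m-", i)] = n_g
            idx[("m+", i)] = n_g + 1
            n_g += 2
        else:
            idx[i] = n_g
            n_g += 1
    dev = []
    for i in range(d):
        if i == k:
            dev.append((idx[("m-", i)], c_lo[i]))
            dev.append((idx[("m+", i)], c[i]))
        else:
            # G continuous at v_i: both one-sided empirical limits matter
            dev.append((idx[i], c_lo[i]))
            dev.append((idx[i], c[i]))
    left_pts = [(idx[i], v[i]) for i in range(k)] + [(idx[("m-", k)], v[k])]
    right_pts = [(idx[("m+", k)], v[k])] + [(idx[i], v[i]) for i in range(k + 1, d)]
    convex = _segments(left_pts)
    concave = _segments(right_pts)
    return _solve(v, c, c_lo, n_g, dev, convex, concave)
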