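"""Naive reference implementations used as independent oracles.

Everything here is written as plain double loops straight from the model
definition, deliberately independent of the package's vectorized code
paths.  Only used by tests.
"""

from __future__ import annotations

import math

import numpy as np


def naive_greedy_thin(points, dmin):
    """Sequential scan keeping a point iff it is >= dmin from all kept."""
    kept = []
    for p in points:
        ok = True
        for q in kept:
            if math.dist(p, q) < dmin:
                ok = False
                break
        if ok:
            kept.append(tuple(p))
    return kept


def naive_point_segment_distance(px, py, ax, ay, bx, by):
    """Distance from a point to a segment via explicit projection."""
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    seg2 = vx * vx + vy * vy
    if seg2 == 0:
        return math.hypot(wx, wy)
    t = max(0.0, min(1.0, (wx * vx + wy * vy) / seg2))
    cx, cy = ax + t * vx, ay + t * vy
    return math.hypot(px - cx, py - cy)


def naive_kernel(dist, phi, u):
    return math.exp(-dist / phi) if dist < u else 0.0


def naive_r(x, y, history, theta, phi, u):
    out = 1.0
    for hx, hy in history:
        out *= 1.0 + (theta - 1.0) * naive_kernel(math.hypot(x - hx, y - hy), phi, u)
    return out


def naive_log_partial_likelihood(
    gamma, beta, theta1, theta2, phi, u,
    mating_months, patterns, centers, e, d, cell_area,
):
    """Lp computed with explicit loops over events and quadrature cells.

    ``patterns`` is a list (per period) of (n, 2) coordinate arrays;
    ``centers``/``e``/``d`` are the masked-cell centres and standardized
    covariate matrices; period 0 has no history.
    """
    gamma = list(np.atleast_1d(gamma))
    beta = list(np.atleast_1d(beta))
    n_cells = len(centers)

    def q_at(c):
        return math.exp(sum(g * e[c][k] for k, g in enumerate(gamma)))

    def b_at(c):
        return math.exp(sum(bb * d[c][k] for k, bb in enumerate(beta)))

    lp = 0.0
    for t, pts in enumerate(patterns):
        if len(pts) == 0:
            continue
        hist = [tuple(p) for p in patterns[t - 1]] if t > 0 else []
        theta = theta2 if (t % 12 + 1) in mating_months else theta1
        denom = 0.0
        r_cells = []
        for c in range(n_cells):
            r_c = naive_r(centers[c][0], centers[c][1], hist, theta, phi, u)
            r_cells.append(r_c)
            denom += q_at(c) * b_at(c) * r_c * cell_area
        for x, y in pts:
            # nearest cell centre = containing cell (axis-aligned grid)
            best, best_d = None, float("inf")
            for c in range(n_cells):
                dd = max(abs(x - centers[c][0]), abs(y - centers[c][1]))
                if dd < best_d:
                    best, best_d = c, dd
            lp += math.log(q_at(best) * b_at(best) * r_cells[best] / denom)
    return lp
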