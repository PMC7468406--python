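"""Numba-compiled Monte-Carlo sweep kernel.

One trial consumes exactly six pre-drawn uniforms (site pick, pool offset
x/y, type layer, contact gate, acceptance), so the kernel and the
pure-Python reference trial in :mod:`rewiremap.rewiring` walk the same RNG
stream and produce bit-identical states.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: uniforms consumed per trial
DRAWS_PER_TRIAL = 6


@njit(cache=True, fastmath=False)
def sweep_kernel(assignment, counts, s_aff, theta, lateral, eta,
                 pool_cx, pool_cy, pool_hw, lgn_nx, lgn_ny, n_layers,
                 v, beta, c_dp, xi_max, t_p, t0, dt_trial, u):
    """Run ``u.shape[0]`` rewiring trials in place; returns swaps accepted.

    assignment : (N, n_sites) int32, mutated
    counts     : (N, C) int32, mutated
    s_aff      : (N, ST) float64 afferent potentials, mutated on swaps
    theta      : (N,) thresholds, frozen for the sweep
    lateral    : (N, ST) summed lateral drive, frozen for the sweep
    eta        : (C, ST) LGN response table
    u          : (n_trials, 6) pre-drawn uniforms
    """
    n_neurons, n_sites = assignment.shape
    n_cells, n_st = eta.shape
    plane = lgn_nx * lgn_ny
    side = 2 * pool_hw + 1
    n_accepted = 0

    for n in range(u.shape[0]):
        t = t0 + n * dt_trial

        gidx = int(u[n, 0] * (n_neurons * n_sites))
        if gidx >= n_neurons * n_sites:       # guard u == 1.0
            gidx = n_neurons * n_sites - 1
        i = gidx // n_sites
        j = gidx - i * n_sites

        dx = int(u[n, 1] * side) - pool_hw
        dy = int(u[n, 2] * side) - pool_hw
        layer = int(u[n, 3] * n_layers)
        if layer >= n_layers:
            layer = n_layers - 1
        cx = (pool_cx[i, j] + dx) % lgn_nx
        cy = (pool_cy[i, j] + dy) % lgn_ny
        cand = layer * plane + cx * lgn_ny + cy

        # age-dependent spine-contact gate
        r = t / (t_p + t)
        g = -xi_max * r * r * r * r
        p_gate = 1.0 / (1.0 + np.exp(-beta * g))
        if u[n, 4] >= p_gate:
            continue

        cur = assignment[i, j]
        if cand == cur:
            continue

        # growth rates before and after the candidate swap; the plasticity
        # products use the deviation of the potential from its homeostatic
        # set point (the long-time mean = threshold), so the weight is
        # (d + L) during suprathreshold episodes and -c (d + L) otherwise
        th = theta[i]
        b_old = 0.0
        b_new = 0.0
        for s in range(n_st):
            d = s_aff[i, s] - th
            lat = lateral[i, s]
            e_old = eta[cur, s]
            e_new = eta[cand, s]
            if d > 0.0:
                w = d + lat
            else:
                w = -c_dp * (d + lat)
            b_old += w * e_old
            d2 = d + v * (e_new - e_old)
            if d2 > 0.0:
                w2 = d2 + lat
            else:
                w2 = -c_dp * (d2 + lat)
            b_new += w2 * e_new
        b_old /= n_st
        b_new /= n_st

        p_acc = 1.0 / (1.0 + np.exp(-beta * (b_new - b_old)))
        if u[n, 5] < p_acc:
            assignment[i, j] = cand
            counts[i, cur] -= 1
            counts[i, cand] += 1
            for s in range(n_st):
                s_aff[i, s] += v * (eta[cand, s] - eta[cur, s])
            n_accepted += 1

    return n_accepted
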