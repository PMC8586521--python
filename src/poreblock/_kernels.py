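"""Numba kernels for exact stochastic simulation and trace rendering.

Kept separate so the jitted functions compile once per process and the public
modules stay importable without triggering compilation at import time.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def _ssa_chunk(exit_rates, cum_prob, state0, t0, t_end, max_events, seed):
    """Simulate the embedded jump chain until t_end or capacity.

    Returns (states, t_entry, dwell, final_state, final_time, flag) where
    flag is 1 if an absorbing state (zero exit rate) was entered.
    The last event is truncated at t_end so events tile the duration exactly.
    """
    np.random.seed(seed)
    states = np.empty(max_events, np.int64)
    t_entry = np.empty(max_events, np.float64)
    dwell = np.empty(max_events, np.float64)
    n = 0
    s = state0
    t = t0
    n_states = exit_rates.shape[0]
    while t < t_end and n < max_events:
        r = exit_rates[s]
        if r <= 0.0:
            return states[:n], t_entry[:n], dwell[:n], s, t, 1
        d = -math.log(1.0 - np.random.random()) / r
        if t + d >= t_end:
            states[n] = s
            t_entry[n] = t
            dwell[n] = t_end - t
            n += 1
            t = t_end
            return states[:n], t_entry[:n], dwell[:n], s, t, 0
        states[n] = s
        t_entry[n] = t
        dwell[n] = d
        n += 1
        t = t + d
        u = np.random.random()
        ns = 0
        while ns < n_states - 1 and cum_prob[s, ns] < u:
            ns += 1
        s = ns
    return states[:n], t_entry[:n], dwell[:n], s, t, 0


@njit(cache=False, fastmath=True)
def _bin_average(states, t_entry, dwell, levels, n_bins, dt):
    """Time-average of the piecewise-constant state current in each bin of
    width dt (area-preserving: sub-bin events contribute their exact area)."""
    out = np.zeros(n_bins, np.float64)
    n = states.shape[0]
    for k in range(n):
        level = levels[states[k]]
        if level == 0.0:
            continue
        t0 = t_entry[k]
        t1 = t0 + dwell[k]
        i0 = int(t0 / dt)
        i1 = int(t1 / dt)
        if i0 >= n_bins:
            continue
        if i1 >= n_bins:
            i1 = n_bins - 1
            t1 = n_bins * dt
        if i0 == i1:
            out[i0] += level * (t1 - t0)
        else:
            out[i0] += level * ((i0 + 1) * dt - t0)
            for i in range(i0 + 1, i1):
                out[i] += level * dt
            out[i1] += level * (t1 - i1 * dt)
    for i in range(n_bins):
        out[i] /= dt
    return out


@njit(cache=False, fastmath=True)
def _occupancy_batches(exit_rates, cum_prob, state0, n_events, n_batches, seed):
    """Time-weighted state occupancy per batch of an SSA run of n_events.

    Returns an (n_batches, n_states) matrix of within-batch time fractions,
    for Monte-Carlo standard errors by batch means.
    """
    np.random.seed(seed)
    n_states = exit_rates.shape[0]
    occ = np.zeros((n_batches, n_states), np.float64)
    per_batch = n_events // n_batches
    s = state0
    for b in range(n_batches):
        total = 0.0
        for _ in range(per_batch):
            r = exit_rates[s]
            if r <= 0.0:
                return occ, 1
            d = -math.log(1.0 - np.random.random()) / r
            occ[b, s] += d
            total += d
            u = np.random.random()
            ns = 0
            while ns < n_states - 1 and cum_prob[s, ns] < u:
                ns += 1
            s = ns
        for j in range(n_states):
            occ[b, j] /= total
    return occ, 0


@njit(cache=False, fastmath=True)
def _dwell_stats(exit_rates, cum_prob, state0, n_events, seed):
    """Per-state total dwell time and visit counts over n_events jumps."""
    np.random.seed(seed)
    n_states = exit_rates.shape[0]
    total = np.zeros(n_states, np.float64)
    visits = np.zeros(n_states, np.int64)
    s = state0
    for _ in range(n_events):
        r = exit_rates[s]
        if r <= 0.0:
            return total, visits, 1
        d = -math.log(1.0 - np.random.random()) / r
        total[s] += d
        visits[s] += 1
        u = np.random.random()
        ns = 0
        while ns < n_states - 1 and cum_prob[s, ns] < u:
            ns += 1
        s = ns
    return total, visits, 0
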