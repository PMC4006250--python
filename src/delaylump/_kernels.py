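"""Compiled single-run kernels for ensemble simulation.

The direct-method SSA and the rejection-method DSSA are also implemented in
pure Python in :mod:`delaylump.simulate` with full event recording; the
kernels here are the same algorithms compiled with numba, recording state
only at the points of a fixed observation grid.  Ensemble comparisons (and
nothing else) run through them; tests assert that kernel and reference
implementations agree distributionally.

Reaction encoding (one row per reaction):

* ``kind``: 0 unimolecular (a = c x), 1 bimolecular distinct (a = c x y),
  2 bimolecular identical pair (a = c x (x-1)), 3 zero-order (a = c),
  4 Hill-repressed (a = c * vmax / (1 + (x / thr)^expo), gated at
  ``x >= min_count``; used by the glycolysis PFK step).
* ``delta``: state change applied at firing (for delayed reactions: the
  reactant removal only).
* delayed reactions reference a product row (applied at completion) and a
  delay sampler: stage-exponential rates, or an inverse-CDF table on a
  uniform probability grid.

The pending-update queue is a binary min-heap on (time, insertion counter),
so simultaneous completions resolve FIFO; when a queued completion precedes
the tentative next-reaction time the tentative firing is rejected and the
completion applied (the memoryless waiting time justifies redrawing).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_kernel", "dssa_kernel"]


@njit(cache=True)
def _propensities(x, kind, rate, r0, r1, hill, a):
    total = 0.0
    for k in range(kind.size):
        c = rate[k]
        kd = kind[k]
        if kd == 0:
            v = c * x[r0[k]]
        elif kd == 1:
            v = c * x[r0[k]] * x[r1[k]]
        elif kd == 2:
            v = c * x[r0[k]] * (x[r0[k]] - 1)
        elif kd == 3:
            v = c
        else:  # Hill repression
            y = x[r0[k]]
            if y < hill[k, 3]:
                v = 0.0
            else:
                v = c * hill[k, 0] / (1.0 + (y / hill[k, 1]) ** hill[k, 2])
        if v < 0.0:
            v = 0.0
        a[k] = v
        total += v
    return total


@njit(cache=True)
def ssa_kernel(seed, x0, t_end, grid, kind, rate, r0, r1, hill, delta):
    np.random.seed(seed)
    S = x0.size
    G = grid.size
    x = x0.copy()
    out = np.zeros((G, S), dtype=np.int64)
    a = np.zeros(kind.size)
    t = 0.0
    gi = 0
    while gi < G:
        total = _propensities(x, kind, rate, r0, r1, hill, a)
        if total <= 0.0:
            while gi < G:
                for s in range(S):
                    out[gi, s] = x[s]
                gi += 1
            break
        t_next = t + np.random.exponential(1.0 / total)
        while gi < G and grid[gi] < t_next:
            for s in range(S):
                out[gi, s] = x[s]
            gi += 1
        if gi >= G or t_next > t_end:
            break
        u = np.random.random() * total
        acc = 0.0
        k = 0
        for kk in range(kind.size):
            acc += a[kk]
            if u <= acc:
                k = kk
                break
        for s in range(S):
            x[s] += delta[k, s]
        t = t_next
    return out


@njit(cache=True)
def _heap_up(ht, hc, hr, i):
    while i > 0:
        p = (i - 1) // 2
        if ht[i] < ht[p] or (ht[i] == ht[p] and hc[i] < hc[p]):
            ht[i], ht[p] = ht[p], ht[i]
            hc[i], hc[p] = hc[p], hc[i]
            hr[i], hr[p] = hr[p], hr[i]
            i = p
        else:
            break


@njit(cache=True)
def _heap_down(ht, hc, hr, size):
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and (ht[l] < ht[m] or (ht[l] == ht[m] and hc[l] < hc[m])):
            m = l
        if r < size and (ht[r] < ht[m] or (ht[r] == ht[m] and hc[r] < hc[m])):
            m = r
        if m == i:
            break
        ht[i], ht[m] = ht[m], ht[i]
        hc[i], hc[m] = hc[m], hc[i]
        hr[i], hr[m] = hr[m], hr[i]
        i = m


@njit(cache=True)
def dssa_kernel(seed, x0, t_end, grid, kind, rate, r0, r1, hill, delta,
                delayed, prod_row, prod_rows, delay_kind,
                stage_start, stage_end, stage_rates,
                table_row, tables, u_grid,
                hist_t, hist_row):
    np.random.seed(seed)
    S = x0.size
    G = grid.size
    K = kind.size
    x = x0.copy()
    out = np.zeros((G, S), dtype=np.int64)
    a = np.zeros(K)

    cap = 64
    n_hist = hist_t.size
    while cap < n_hist + 16:
        cap *= 2
    ht = np.empty(cap)
    hc = np.empty(cap, dtype=np.int64)
    hr = np.empty(cap, dtype=np.int64)
    size = 0
    counter = 0
    for i in range(n_hist):
        ht[size] = hist_t[i]
        hc[size] = counter
        hr[size] = hist_row[i]
        size += 1
        counter += 1
        _heap_up(ht, hc, hr, size - 1)

    t = 0.0
    gi = 0
    while gi < G:
        total = _propensities(x, kind, rate, r0, r1, hill, a)
        if total <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / total)
        t_comp = ht[0] if size > 0 else np.inf
        if t_comp <= t_next:
            # a queued completion preempts the tentative firing
            event_t = t_comp
            if event_t > t_end:
                event_t = np.inf
        else:
            event_t = t_next
        while gi < G and grid[gi] < event_t:
            for s in range(S):
                out[gi, s] = x[s]
            gi += 1
        if gi >= G or event_t > t_end or not np.isfinite(event_t):
            break
        if t_comp <= t_next:
            row = hr[0]
            size -= 1
            ht[0] = ht[size]
            hc[0] = hc[size]
            hr[0] = hr[size]
            _heap_down(ht, hc, hr, size)
            for s in range(S):
                x[s] += prod_rows[row, s]
            t = t_comp
        else:
            u = np.random.random() * total
            acc = 0.0
            k = 0
            for kk in range(K):
                acc += a[kk]
                if u <= acc:
                    k = kk
                    break
            for s in range(S):
                x[s] += delta[k, s]
            t = t_next
            if delayed[k]:
                if delay_kind[k] == 0:
                    tau = 0.0
                    for i in range(stage_start[k], stage_end[k]):
                        tau += np.random.exponential(1.0 / stage_rates[i])
                else:
                    u2 = np.random.random()
                    if u2 > u_grid[-1]:
                        u2 = u_grid[-1]
                    j = np.searchsorted(u_grid, u2)
                    if j == 0:
                        tau = tables[table_row[k], 0]
                    else:
                        lo = u_grid[j - 1]
                        hi = u_grid[j]
                        w = (u2 - lo) / (hi - lo)
                        tau = (1.0 - w) * tables[table_row[k], j - 1] + w * tables[table_row[k], j]
                if size >= cap:
                    new_cap = cap * 2
                    nt = np.empty(new_cap)
                    nc = np.empty(new_cap, dtype=np.int64)
                    nr = np.empty(new_cap, dtype=np.int64)
                    for i in range(size):
                        nt[i] = ht[i]
                        nc[i] = hc[i]
                        nr[i] = hr[i]
                    ht, hc, hr, cap = nt, nc, nr, new_cap
                ht[size] = t + tau
                hc[size] = counter
                hr[size] = prod_row[k]
                size += 1
                counter += 1
                _heap_up(ht, hc, hr, size - 1)
    return out
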