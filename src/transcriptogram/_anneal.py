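"""Compiled inner loops for list-ordering by simulated annealing.

The list matrix is never materialised: the adjacency matrix stays in gene
coordinates and the current permutation ``order`` maps list positions to
gene indices, so a position swap is two integer writes.  The neighbourhood
cost couples a pair (i, j) only to list positions i±1 and j±1, so the exact
cost change of a swap touches at most six rows of the list matrix.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def full_cost(adj, order, dpow):
    """Neighbourhood cost of a permutation, summed over pairs i < j.

    Out-of-range neighbour terms at the list boundaries are omitted.
    ``dpow[d]`` holds d**alpha.
    """
    n = order.shape[0]
    total = 0.0
    for i in range(n - 1):
        gi = order[i]
        for j in range(i + 1, n):
            gj = order[j]
            a = adj[gi, gj]
            t = 0.0
            if i + 1 < n:
                t += abs(a - adj[order[i + 1], gj])
            if i - 1 >= 0:
                t += abs(a - adj[order[i - 1], gj])
            if j + 1 < n:
                t += abs(a - adj[gi, order[j + 1]])
            if j - 1 >= 0:
                t += abs(a - adj[gi, order[j - 1]])
            total += dpow[j - i] * t
    return total


@njit(cache=True, inline="always")
def _pair_term(adj, order, i, j):
    # Eq. term for the (i, j) pair; symmetric in i and j because adj is.
    n = order.shape[0]
    a = adj[order[i], order[j]]
    t = 0.0
    if i + 1 < n:
        t += abs(a - adj[order[i + 1], order[j]])
    if i - 1 >= 0:
        t += abs(a - adj[order[i - 1], order[j]])
    if j + 1 < n:
        t += abs(a - adj[order[i], order[j + 1]])
    if j - 1 >= 0:
        t += abs(a - adj[order[i], order[j - 1]])
    return t


@njit(cache=True)
def _touched_cost(adj, order, dpow, touched, n_touched, is_touched):
    """Cost restricted to pairs with at least one index in `touched`."""
    n = order.shape[0]
    total = 0.0
    for k in range(n_touched):
        s = touched[k]
        for j in range(n):
            if j == s:
                continue
            if is_touched[j] and j < s:
                continue  # touched-touched pair already counted from the smaller index
            d = j - s if j > s else s - j
            total += dpow[d] * _pair_term(adj, order, s, j)
    return total


@njit(cache=True)
def _build_touched(a, b, n, touched, is_touched):
    n_touched = 0
    for cand in (a - 1, a, a + 1, b - 1, b, b + 1):
        if 0 <= cand < n and not is_touched[cand]:
            is_touched[cand] = True
            touched[n_touched] = cand
            n_touched += 1
    return n_touched


@njit(cache=True)
def delta_swap(adj, order, dpow, a, b):
    """Exact cost change of swapping list positions a and b (order unchanged)."""
    n = order.shape[0]
    touched = np.empty(6, np.int64)
    is_touched = np.zeros(n, np.bool_)
    n_touched = _build_touched(a, b, n, touched, is_touched)
    before = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
    order[a], order[b] = order[b], order[a]
    after = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
    order[a], order[b] = order[b], order[a]
    return after - before


@njit(cache=True)
def sample_swap_deltas(adj, order, dpow, n_samples, seed):
    """|dF| of random swaps from a fixed state; used to auto-scale T."""
    np.random.seed(seed)
    n = order.shape[0]
    out = np.empty(n_samples)
    for k in range(n_samples):
        a = np.random.randint(0, n)
        b = np.random.randint(0, n - 1)
        if b >= a:
            b += 1
        out[k] = abs(delta_swap(adj, order, dpow, a, b))
    return out


@njit(cache=True)
def anneal_run(adj, dpow, order, t_initial, t_decrement, steps_per_level, t_final, seed):
    """One annealing restart followed by a zero-temperature polish.

    Returns (best_order, best_cost, running_min_trace) where the trace holds
    the best cost seen at the end of each temperature level.  `order` is
    mutated in place as working memory.
    """
    np.random.seed(seed)
    n = order.shape[0]
    touched = np.empty(6, np.int64)
    is_touched = np.zeros(n, np.bool_)

    cost = full_cost(adj, order, dpow)
    best_cost = cost
    best_order = order.copy()

    n_levels = int(np.ceil((t_initial - t_final) / t_decrement)) + 1
    trace = np.empty(n_levels)
    level = 0
    t = t_initial
    while t > t_final and t > 0.0:
        for _ in range(steps_per_level):
            for _ in range(n):  # one Monte-Carlo step: n attempted exchanges
                a = np.random.randint(0, n)
                b = np.random.randint(0, n - 1)
                if b >= a:
                    b += 1
                n_touched = _build_touched(a, b, n, touched, is_touched)
                before = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
                order[a], order[b] = order[b], order[a]
                after = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
                for k in range(n_touched):
                    is_touched[touched[k]] = False
                d = after - before
                if d <= 0.0 or np.random.random() < np.exp(-d / t):
                    cost += d
                    if cost < best_cost - 1e-9:
                        best_cost = cost
                        best_order[:] = order
                else:
                    order[a], order[b] = order[b], order[a]
        trace[level] = best_cost
        level += 1
        t -= t_decrement

    # zero-temperature polish of the best state: accept dF <= 0 until a full
    # Monte-Carlo step brings no strict improvement
    order[:] = best_order
    cost = best_cost
    improved = True
    while improved:
        improved = False
        for _ in range(n):
            a = np.random.randint(0, n)
            b = np.random.randint(0, n - 1)
            if b >= a:
                b += 1
            n_touched = _build_touched(a, b, n, touched, is_touched)
            before = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
            order[a], order[b] = order[b], order[a]
            after = _touched_cost(adj, order, dpow, touched, n_touched, is_touched)
            for k in range(n_touched):
                is_touched[touched[k]] = False
            d = after - before
            if d <= 0.0:
                cost += d
                if d < -1e-12:
                    improved = True
            else:
                order[a], order[b] = order[b], order[a]
    best_order[:] = order
    best_cost = full_cost(adj, order, dpow)  # re-anchor against float drift
    return best_order, best_cost, trace[:level]
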