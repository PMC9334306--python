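"""Numba kernels for exact TSP computations at desk scale (N <= 22).

Three routines operate on a full-precision Euclidean distance matrix:

* :func:`held_karp` — exact minimum closed-tour length and one optimal tour
  via dynamic programming over subsets (O(2^N N^2) time, O(2^N N) memory).
* :func:`bnb_tsp` — exact branch-and-bound with a fixed, documented search
  order: nearest-neighbour child ordering, a 2-opt-improved nearest-
  neighbour initial incumbent, and a minimum-spanning-tree lower bound over
  the unvisited cities plus the two path endpoints.  Returns the optimum
  and the number of search nodes expanded; the node count is the package's
  deterministic solver-effort measure for TSP.
* :func:`count_tours_within` — number of directed tours starting at city 0
  with length <= limit, enumeration halting at a cap, pruned with the same
  MST bound.

All tours are closed Hamiltonian cycles through every city.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def held_karp(d):
    """Exact minimum closed tour. Returns (optimum, tour as city indices)."""
    n = d.shape[0]
    m = n - 1
    full = (1 << m) - 1
    dp = np.full((full + 1, m), np.inf)
    par = np.full((full + 1, m), -1, np.int16)
    for j in range(m):
        dp[1 << j, j] = d[0, j + 1]
    for mask in range(1, full + 1):
        for j in range(m):
            if (mask >> j) & 1 == 0:
                continue
            cur = dp[mask, j]
            if cur == np.inf:
                continue
            for k in range(m):
                if (mask >> k) & 1:
                    continue
                nm = mask | (1 << k)
                nd = cur + d[j + 1, k + 1]
                if nd < dp[nm, k]:
                    dp[nm, k] = nd
                    par[nm, k] = j
    best = np.inf
    bj = -1
    for j in range(m):
        tot = dp[full, j] + d[j + 1, 0]
        if tot < best:
            best = tot
            bj = j
    tour = np.empty(n, np.int64)
    tour[0] = 0
    mask = full
    j = bj
    for pos in range(n - 1, 0, -1):
        tour[pos] = j + 1
        pj = par[mask, j]
        mask ^= 1 << j
        j = pj
    return best, tour


@njit(cache=True)
def _nn_tour(d):
    n = d.shape[0]
    visited = np.zeros(n, np.bool_)
    visited[0] = True
    last = 0
    tour = np.empty(n, np.int64)
    tour[0] = 0
    for step in range(1, n):
        bestd = np.inf
        bestu = -1
        for u in range(n):
            if not visited[u] and d[last, u] < bestd:
                bestd = d[last, u]
                bestu = u
        visited[bestu] = True
        tour[step] = bestu
        last = bestu
    return tour


@njit(cache=True)
def _tour_length(d, tour):
    n = len(tour)
    total = 0.0
    for i in range(n):
        total += d[tour[i], tour[(i + 1) % n]]
    return total


@njit(cache=True)
def _two_opt(d, tour):
    """First-improvement 2-opt to a local optimum (deterministic sweep)."""
    n = len(tour)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                a, b = tour[i], tour[i + 1]
                c, e = tour[j], tour[(j + 1) % n]
                delta = d[a, c] + d[b, e] - d[a, b] - d[c, e]
                if delta < -1e-9:
                    lo, hi = i + 1, j
                    while lo < hi:
                        tour[lo], tour[hi] = tour[hi], tour[lo]
                        lo += 1
                        hi -= 1
                    improved = True
    return tour


@njit(cache=True)
def _mst_bound(d, visited, last):
    """MST over {last, 0} and the unvisited cities: a lower bound on the
    cost of completing the path from `last` through all unvisited back to 0."""
    n = d.shape[0]
    # vertex list: last, city 0 (if distinct), all unvisited
    verts = np.empty(n + 1, np.int64)
    k = 0
    verts[k] = last
    k += 1
    if last != 0:
        verts[k] = 0
        k += 1
    for u in range(n):
        if not visited[u]:
            verts[k] = u
            k += 1
    if k <= 1:
        return 0.0
    in_tree = np.zeros(k, np.bool_)
    dist = np.full(k, np.inf)
    dist[0] = 0.0
    total = 0.0
    for _ in range(k):
        best = np.inf
        bi = -1
        for i in range(k):
            if not in_tree[i] and dist[i] < best:
                best = dist[i]
                bi = i
        in_tree[bi] = True
        total += best
        vb = verts[bi]
        for i in range(k):
            if not in_tree[i]:
                w = d[vb, verts[i]]
                if w < dist[i]:
                    dist[i] = w
    return total




@njit
def _min_out(d):
    n = d.shape[0]
    out = np.empty(n)
    for i in range(n):
        b = np.inf
        for j in range(n):
            if j != i and d[i, j] < b:
                b = d[i, j]
        out[i] = b
    return out


@njit
def _fill_sorted_children(d, visited, last, cand_row, dist_row):
    """Unvisited cities into preallocated buffers, nearest-first (stable
    insertion sort; no allocation).  Returns the child count."""
    n = d.shape[0]
    cnt = 0
    for u in range(n):
        if not visited[u]:
            du = d[last, u]
            j = cnt
            while j > 0 and dist_row[j - 1] > du:
                dist_row[j] = dist_row[j - 1]
                cand_row[j] = cand_row[j - 1]
                j -= 1
            dist_row[j] = du
            cand_row[j] = u
            cnt += 1
    return cnt


@njit
def _bnb_rec(d, minout, visited, path, depth, g, summin, best, nodes, cand, dist, node_cap):
    # summin = sum of min outgoing edges over unvisited cities (quick bound)
    if nodes[0] >= node_cap:
        return
    nodes[0] += 1
    n = d.shape[0]
    last = path[depth - 1]
    if depth == n:
        tot = g + d[last, 0]
        if tot < best[0]:
            best[0] = tot
        return
    nearest = np.inf
    for u in range(n):
        if not visited[u] and d[last, u] < nearest:
            nearest = d[last, u]
    if g + nearest + summin >= best[0]:
        return
    if g + _mst_bound(d, visited, last) >= best[0]:
        return
    cnt = _fill_sorted_children(d, visited, last, cand[depth], dist[depth])
    for t in range(cnt):
        u = cand[depth, t]
        du = dist[depth, t]
        visited[u] = True
        path[depth] = u
        _bnb_rec(d, minout, visited, path, depth + 1, g + du, summin - minout[u], best, nodes, cand, dist, node_cap)
        visited[u] = False


@njit
def bnb_tsp(d, ub=np.inf, node_cap=1 << 62):
    """Exact branch-and-bound. Returns (optimum, nodes expanded).

    ``ub`` seeds the incumbent.  With the default (infinity) the incumbent
    starts from a 2-opt-improved nearest-neighbour tour and the search both
    finds and certifies the optimum; passing a known optimum turns the node
    count into the cost of *certifying* it.  ``node_cap`` truncates the
    search (and the returned count) at a fixed ceiling; exactness of the
    returned optimum is only guaranteed when the cap is not reached or the
    incumbent was already optimal.
    """
    n = d.shape[0]
    tour = _two_opt(d, _nn_tour(d))
    best = np.empty(1)
    best[0] = min(_tour_length(d, tour), ub)
    nodes = np.zeros(1, np.int64)
    visited = np.zeros(n, np.bool_)
    visited[0] = True
    path = np.empty(n, np.int64)
    path[0] = 0
    minout = _min_out(d)
    summin = 0.0
    for u in range(1, n):
        summin += minout[u]
    cand = np.empty((n, n), np.int64)
    dist = np.empty((n, n))
    _bnb_rec(d, minout, visited, path, 1, 0.0, summin, best, nodes, cand, dist, node_cap)
    return best[0], nodes[0]


@njit(cache=True)
def _completion_table(d):
    """e[R, j] = exact minimum cost of a path that starts at city j+1,
    visits every city in bitmask R (over cities 1..n-1), and ends at 0.

    One subset-DP pass, same asymptotic cost as Held-Karp.  Used as a
    perfect admissible completion bound when enumerating tours, which makes
    the enumeration tree proportional to the number of tours found."""
    n = d.shape[0]
    m = n - 1
    size = 1 << m
    e = np.full((size, m), np.inf)
    for j in range(m):
        e[0, j] = d[j + 1, 0]
    for R in range(1, size):
        for j in range(m):
            if (R >> j) & 1:
                continue
            best = np.inf
            for k in range(m):
                if (R >> k) & 1:
                    v = d[j + 1, k + 1] + e[R ^ (1 << k), k]
                    if v < best:
                        best = v
            e[R, j] = best
    return e


@njit
def _count_rec(d, e, remaining, path, depth, g, limit, cap, acc, cand, dist):
    # acc[0] = tours found, acc[1] = nodes visited
    if acc[0] >= cap:
        return
    acc[1] += 1
    n = d.shape[0]
    last = path[depth - 1]
    if depth == n:
        if g + d[last, 0] <= limit:
            acc[0] += 1
        return
    # exact completion bound: only prefixes with a valid completion survive
    if last > 0 and g + e[remaining, last - 1] > limit:
        return
    cnt = 0
    for k in range(n - 1):
        if (remaining >> k) & 1:
            u = k + 1
            du = d[last, u]
            j = cnt
            while j > 0 and dist[depth, j - 1] > du:
                dist[depth, j] = dist[depth, j - 1]
                cand[depth, j] = cand[depth, j - 1]
                j -= 1
            dist[depth, j] = du
            cand[depth, j] = u
            cnt += 1
    for t in range(cnt):
        u = cand[depth, t]
        du = dist[depth, t]
        path[depth] = u
        _count_rec(
            d, e, remaining ^ (1 << (u - 1)), path, depth + 1, g + du, limit, cap, acc, cand, dist
        )


@njit
def count_tours_within(d, limit, cap):
    """Count directed tours from city 0 with length <= limit, up to cap.

    Returns (count, nodes visited).  Reversed tours are counted as distinct;
    the fixed start city removes the rotation symmetry only.  The search is
    pruned with an exact subset-DP completion bound, so its cost scales with
    the number of tours reported, not with the near-miss space.
    """
    n = d.shape[0]
    e = _completion_table(d)
    acc = np.zeros(2, np.int64)
    path = np.empty(n, np.int64)
    path[0] = 0
    full = (1 << (n - 1)) - 1
    cand = np.empty((n, n), np.int64)
    dist = np.empty((n, n))
    _count_rec(d, e, full, path, 1, 0.0, limit, cap, acc, cand, dist)
    return acc[0], acc[1]
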