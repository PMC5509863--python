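"""Numba kernels for the dynamic time alignment kernel (DTAK) and the
segment-boundary dynamic program.

The DTAK between two frame ranges is computed on the Gaussian frame kernel
``F`` with the (1, 2, 1)-weighted recursion

    u(0, 0) = 2 f(0, 0)
    u(p, q) = max( u(p-1, q) + f(p, q),
                   u(p-1, q-1) + 2 f(p, q),
                   u(p, q-1) + f(p, q) )

and normalization ``tau = u(n_a - 1, n_b - 1) / (n_a + n_b)``, which bounds
``tau`` in (0, 1] for kernels with entries in (0, 1] and makes
``tau(Q, Q) = 1`` whenever ``F`` has unit diagonal.

The candidate-segment routines fill, for every start frame ``s`` and length
``l <= l_max``, the DTAK against every current segment in a single DP sweep
per ``(s, segment)`` pair by reading the value off each completed DP row.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dtak_pair(F, a0, a1, b0, b1):
    """DTAK between frame ranges [a0, a1) and [b0, b1) of kernel F."""
    na = a1 - a0
    nb = b1 - b0
    prev = np.empty(nb)
    curr = np.empty(nb)
    prev[0] = 2.0 * F[a0, b0]
    for q in range(1, nb):
        prev[q] = prev[q - 1] + F[a0, b0 + q]
    for p in range(1, na):
        curr[0] = prev[0] + F[a0 + p, b0]
        for q in range(1, nb):
            f = F[a0 + p, b0 + q]
            best = prev[q] + f
            diag = prev[q - 1] + 2.0 * f
            if diag > best:
                best = diag
            left = curr[q - 1] + f
            if left > best:
                best = left
            curr[q] = best
        prev, curr = curr, prev
    return prev[nb - 1] / (na + nb)


@njit(cache=True)
def dtak_matrix(F, starts, ends):
    """Symmetric M x M DTAK matrix between the segments [starts[i], ends[i])."""
    M = starts.shape[0]
    T = np.empty((M, M))
    for i in range(M):
        for j in range(i, M):
            t = dtak_pair(F, starts[i], ends[i], starts[j], ends[j])
            T[i, j] = t
            T[j, i] = t
    return T


@njit(cache=True)
def candidate_cross_tau(F, starts, ends, l_max):
    """DTAK of every candidate segment [s, s+l) against every current segment.

    Returns ``out[s, l-1, j] = tau([s, s+l), segment j)`` (zero where
    ``s + l > N``).  For each (start, segment) pair one DP table is filled
    row by row; completing row ``p`` yields the value for length ``p + 1``.
    """
    N = F.shape[0]
    M = starts.shape[0]
    out = np.zeros((N, l_max, M))
    for s in range(N):
        L = min(l_max, N - s)
        for j in range(M):
            b0 = starts[j]
            nb = ends[j] - starts[j]
            prev = np.empty(nb)
            curr = np.empty(nb)
            prev[0] = 2.0 * F[s, b0]
            for q in range(1, nb):
                prev[q] = prev[q - 1] + F[s, b0 + q]
            out[s, 0, j] = prev[nb - 1] / (1 + nb)
            for p in range(1, L):
                curr[0] = prev[0] + F[s + p, b0]
                for q in range(1, nb):
                    f = F[s + p, b0 + q]
                    best = prev[q] + f
                    diag = prev[q - 1] + 2.0 * f
                    if diag > best:
                        best = diag
                    left = curr[q - 1] + f
                    if left > best:
                        best = left
                    curr[q] = best
                out[s, p, j] = curr[nb - 1] / (p + 1 + nb)
                tmp = prev
                prev = curr
                curr = tmp
    return out


@njit(cache=True)
def candidate_self_tau(F, l_max):
    """Self-DTAK ``out[s, l-1] = tau([s, s+l), [s, s+l))`` for all starts.

    Because the DP cell (p, q) depends only on cells with smaller indices,
    the diagonal entries of one L x L table give the values for all lengths.
    """
    N = F.shape[0]
    out = np.ones((N, l_max))
    for s in range(N):
        L = min(l_max, N - s)
        U = np.empty((L, L))
        U[0, 0] = 2.0 * F[s, s]
        for q in range(1, L):
            U[0, q] = U[0, q - 1] + F[s, s + q]
        for p in range(1, L):
            U[p, 0] = U[p - 1, 0] + F[s + p, s]
            for q in range(1, L):
                f = F[s + p, s + q]
                best = U[p - 1, q] + f
                diag = U[p - 1, q - 1] + 2.0 * f
                if diag > best:
                    best = diag
                left = U[p, q - 1] + f
                if left > best:
                    best = left
                U[p, q] = best
        for l in range(1, L + 1):
            out[s, l - 1] = U[l - 1, l - 1] / (2 * l)
    return out


@njit(cache=True)
def boundary_dp(D, l_min, l_max, N, K, cum_w, max_span):
    """Optimal segmentation by DP over end positions.

    ``D[s, l-1, k]`` is the cost of assigning segment [s, s+l) to cluster k.
    ``V(v) = min over l in [l_min, min(l_max, v)], k of V(v-l) + D[v-l, l-1, k]``.
    Ties prefer the longer segment, then the smaller cluster index (the loop
    order below combined with strict improvement enforces exactly that).

    ``cum_w``/``max_span`` impose an extra weighted-length cap: a candidate
    with ``cum_w[v] - cum_w[v-l] > max_span`` is skipped unless it is a
    single unit (so the DP always stays feasible).  With unit weights and
    ``max_span >= N`` the cap is inert.
    """
    INF = np.inf
    V = np.full(N + 1, INF)
    V[0] = 0.0
    best_l = np.full(N + 1, -1, dtype=np.int64)
    best_k = np.full(N + 1, -1, dtype=np.int64)
    for v in range(1, N + 1):
        top = min(l_max, v)
        best = INF
        bl = -1
        bk = -1
        for l in range(top, l_min - 1, -1):
            if l > 1 and cum_w[v] - cum_w[v - l] > max_span:
                continue
            pv = V[v - l]
            if pv == INF:
                continue
            for k in range(K):
                val = pv + D[v - l, l - 1, k]
                if val < best:
                    best = val
                    bl = l
                    bk = k
        V[v] = best
        best_l[v] = bl
        best_k[v] = bk
    return V, best_l, best_k
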