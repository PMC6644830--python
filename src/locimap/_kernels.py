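"""Numba kernels: layer-skipping forward/backward DP and exhaustive DFS.

All kernels work on flattened per-locus candidate lists (``off``/``cand``)
so that color filtering, forced mappings and spot exclusions are encoded
purely in ``-inf`` log-penalties.  The DP consumes a precomputed
propagator cache (per locus pair within a skip window, the matrix of
Gaussian-chain factors between their candidate spots), so re-evaluations
with different penalties — optimizer iterations and series terms — pay
only multiply-adds.  Weights are accumulated in a scaled linear domain
with one log-offset per locus layer, which keeps 300-locus problems
inside float range.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def dp_engine(logqm, off, cand, logq, win_lo, pc_off, pc_val, pc_logc, thresh):
    """Forward/backward DP over locus layers with missing-locus skips.

    Parameters
    ----------
    logqm : (N,) log missing penalty per locus (-inf: locus cannot be missing)
    off, cand : flattened candidate spot lists per locus
    logq : per-candidate log spot penalty (-inf: candidate disallowed)
    win_lo : (N,) lowest source layer within the skip window of each layer
    pc_off : (N, W) flat offset of the propagator block for pair
        (i, j = i-1-w), -1 when absent
    pc_val : propagator blocks, block (i, j) row-major (cand_i x cand_j)
    pc_logc : (N, W) log normalization of each pair's propagator
    thresh : contributions more than ``thresh`` nats below the realized
        layer maximum are dropped (set near 700 = float underflow)

    Returns
    -------
    (log_Z_forward, log_Z_backward, log_Z_map_flat)
    """
    N = logqm.shape[0]
    K = cand.shape[0]

    pre = np.empty(N + 1)
    pre[0] = 0.0
    for i in range(N):
        pre[i + 1] = pre[i] + logqm[i]
    suf = np.empty(N + 1)
    suf[N] = 0.0
    for i in range(N - 1, -1, -1):
        suf[i] = suf[i + 1] + logqm[i]

    maxlq = np.full(N, NEG_INF)
    for i in range(N):
        for m in range(off[i], off[i + 1]):
            if logq[m] > maxlq[i]:
                maxlq[i] = logq[m]

    # ---- forward: F includes the spot penalty of its own layer ----
    F = np.zeros(K)
    S = np.full(N, NEG_INF)
    ub = np.empty(N)
    skipv = np.empty(N)
    for i in range(N):
        o0 = off[i]
        o1 = off[i + 1]
        nc = o1 - o0
        if nc == 0:
            continue
        lo = win_lo[i]
        best = pre[i]
        for j in range(lo, i):
            ub[j] = NEG_INF
        skip = 0.0
        for j in range(i - 1, lo - 1, -1):
            if skip == NEG_INF:
                break
            skipv[j] = skip
            if S[j] != NEG_INF and pc_off[i, i - 1 - j] >= 0:
                ub[j] = S[j] + skip + pc_logc[i, i - 1 - j]
                if ub[j] > best:
                    best = ub[j]
            skip += logqm[j]
        ref = best
        if ref == NEG_INF:
            continue
        acc = np.zeros(nc)
        cur_max = NEG_INF
        if pre[i] != NEG_INF:
            v = math.exp(pre[i] - ref)
            for k in range(nc):
                acc[k] += v
            cur_max = pre[i]
        order = np.argsort(ub[lo:i])
        for t in range(i - lo - 1, -1, -1):
            j = lo + order[t]
            if ub[j] == NEG_INF or ub[j] < cur_max - thresh:
                break
            w = math.exp(S[j] + skipv[j] + pc_logc[i, i - 1 - j] - ref)
            b = pc_off[i, i - 1 - j]
            oj = off[j]
            ncj = off[j + 1] - oj
            amax = 0.0
            for k in range(nc):
                s = cand[o0 + k]
                tt = 0.0
                for m in range(ncj):
                    if cand[oj + m] != s:
                        tt += F[oj + m] * pc_val[b + k * ncj + m]
                acc[k] += w * tt
                if acc[k] > amax:
                    amax = acc[k]
            if amax > 0.0:
                lm = ref + math.log(amax)
                if lm > cur_max:
                    cur_max = lm
        mx = 0.0
        for k in range(nc):
            acc[k] *= math.exp(logq[o0 + k])
            if acc[k] > mx:
                mx = acc[k]
        if mx > 0.0:
            S[i] = ref + math.log(mx)
            for k in range(nc):
                F[o0 + k] = acc[k] / mx

    log_zf = pre[N]
    for i in range(N):
        if S[i] != NEG_INF and suf[i + 1] != NEG_INF:
            tot = 0.0
            for m in range(off[i], off[i + 1]):
                tot += F[m]
            if tot > 0.0:
                log_zf = np.logaddexp(log_zf, S[i] + math.log(tot) + suf[i + 1])

    # ---- backward: B excludes the spot penalty of its own layer ----
    B = np.zeros(K)
    BQ = np.zeros(K)
    T = np.full(N, NEG_INF)
    for i in range(N - 1, -1, -1):
        o0 = off[i]
        o1 = off[i + 1]
        nc = o1 - o0
        if nc == 0:
            continue
        hi = i
        for j in range(i + 1, N):
            if win_lo[j] > i:
                break
            hi = j
        best = suf[i + 1]
        for j in range(i + 1, hi + 1):
            ub[j] = NEG_INF
        skip = 0.0
        for j in range(i + 1, hi + 1):
            if skip == NEG_INF:
                break
            skipv[j] = skip
            if T[j] != NEG_INF and pc_off[j, j - 1 - i] >= 0:
                ub[j] = T[j] + skip + pc_logc[j, j - 1 - i] + maxlq[j]
                if ub[j] > best:
                    best = ub[j]
            skip += logqm[j]
        ref = best
        if ref == NEG_INF:
            continue
        acc = np.zeros(nc)
        cur_max = NEG_INF
        if suf[i + 1] != NEG_INF:
            v = math.exp(suf[i + 1] - ref)
            for k in range(nc):
                acc[k] += v
            cur_max = suf[i + 1]
        order = np.argsort(ub[i + 1 : hi + 1])
        for t in range(hi - i - 1, -1, -1):
            j = i + 1 + order[t]
            if ub[j] == NEG_INF or ub[j] < cur_max - thresh:
                break
            w = math.exp(T[j] + skipv[j] + pc_logc[j, j - 1 - i] - ref)
            b = pc_off[j, j - 1 - i]
            oj = off[j]
            ncj = off[j + 1] - oj
            amax = 0.0
            for k in range(nc):
                s = cand[o0 + k]
                tt = 0.0
                for m in range(ncj):
                    if cand[oj + m] != s:
                        tt += BQ[oj + m] * pc_val[b + m * nc + k]
                acc[k] += w * tt
                if acc[k] > amax:
                    amax = acc[k]
            if amax > 0.0:
                lm = ref + math.log(amax)
                if lm > cur_max:
                    cur_max = lm
        mx = 0.0
        for k in range(nc):
            if acc[k] > mx:
                mx = acc[k]
        if mx > 0.0:
            T[i] = ref + math.log(mx)
            for k in range(nc):
                B[o0 + k] = acc[k] / mx
                BQ[o0 + k] = B[o0 + k] * math.exp(logq[o0 + k])

    log_zb = pre[N]
    for i in range(N):
        if T[i] != NEG_INF and pre[i] != NEG_INF:
            tot = 0.0
            for m in range(off[i], off[i + 1]):
                tot += BQ[m]
            if tot > 0.0:
                log_zb = np.logaddexp(log_zb, pre[i] + T[i] + math.log(tot))

    # ---- per-mapping partition terms ----
    log_zmap = np.full(K, NEG_INF)
    for i in range(N):
        if S[i] == NEG_INF or T[i] == NEG_INF:
            continue
        for m in range(off[i], off[i + 1]):
            v = F[m] * B[m]
            if v > 0.0:
                log_zmap[m] = S[i] + T[i] + math.log(v)

    return log_zf, log_zb, log_zmap


@njit(cache=True)
def _prop_coeff(gap, n_l, l_p, rho):
    """Gaussian-chain coefficients for genomic gap (kb): sigma = exp(logC - a*r2)."""
    if gap < l_p:
        R = gap / n_l
    else:
        R = l_p ** (1.0 - rho) / n_l * gap**rho
    a = 1.5 / (R * R)
    logC = 1.5 * math.log(a / math.pi)
    return a, logC


@njit(cache=True)
def oracle_dfs(coords, logqm, off, cand, logq, D2, n_l, l_p, rho, max_leaves):
    """Exact partition function by DFS over globally injective assignments.

    Returns (log_Z, log_Z_map) with log_Z_map of shape (N, M + 1); the last
    column is the missing outcome.  Returns log_Z = nan when the leaf cap
    is exceeded.  Deliberately independent of the DP machinery (recomputes
    propagators from scratch, no caching, no windows).
    """
    N = coords.shape[0]
    M = D2.shape[0]
    used = np.zeros(M, np.bool_)
    assign = np.full(N, -2, np.int64)  # -2 unset, -1 missing, >=0 spot
    choice = np.zeros(N, np.int64)
    lastm = np.full(N + 1, -1, np.int64)
    lw = np.zeros(N + 1)

    log_z = NEG_INF
    log_zmap = np.full((N, M + 1), NEG_INF)
    leaves = 0

    i = 0
    while i >= 0:
        if i == N:
            w = lw[N]
            if w != NEG_INF:
                leaves += 1
                if leaves > max_leaves:
                    log_z = np.nan
                    break
                log_z = np.logaddexp(log_z, w)
                for l in range(N):
                    col = assign[l] if assign[l] >= 0 else M
                    log_zmap[l, col] = np.logaddexp(log_zmap[l, col], w)
            i -= 1
            continue
        if assign[i] >= 0:
            used[assign[i]] = False
        assign[i] = -2
        nc = off[i + 1] - off[i]
        c = choice[i]
        if c > nc:  # candidates exhausted (nc = missing option index)
            choice[i] = 0
            i -= 1
            continue
        choice[i] = c + 1
        if c == nc:  # missing
            w = logqm[i]
            if lw[i] + w != NEG_INF:
                assign[i] = -1
                lastm[i + 1] = lastm[i]
                lw[i + 1] = lw[i] + w
                i += 1
            continue
        s = cand[off[i] + c]
        if used[s]:
            continue
        w = logq[off[i] + c]
        j = lastm[i]
        if j >= 0:
            a, logC = _prop_coeff(coords[i] - coords[j], n_l, l_p, rho)
            w += logC - a * D2[s, assign[j]]
        if lw[i] + w != NEG_INF:
            assign[i] = s
            used[s] = True
            lastm[i + 1] = i
            lw[i + 1] = lw[i] + w
            i += 1

    return log_z, log_zmap
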