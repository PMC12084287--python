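"""Compiled direct-method SSA kernel for the reaction-transport process.

One well-mixed voxel per cell; per-voxel propensities are grouped behind a
binary sum tree over voxels, so each event costs one tree descent, a short
linear scan over the eleven voxel channels and a localised propensity
update of the one or two voxels the event touched.  The channel scan is
ordered by expected traffic (the Dll1 spawn/transport and Notch channels
dominate in patterned states).  Uniform variates come from a seeded
xorshift128+ generator (initialised through SplitMix64), which keeps the
per-event cost low; floating-point drift in the tree is curbed by periodic
full rebuilds.
"""

import numpy as np
from numba import njit

# channel indices:
# 0 n->n+D  1 N->N+M  2 M->M+P  3 0->n  4..8 degradation D,N,M,P,n
# 9 D->D+Din  10 Din(k)->N(l)|sink
# species: 0 D, 1 N, 2 M, 3 P, 4 n, 5 Din

_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _rng_u01(state):
    # xorshift128+ (Vigna); state is a 2-element uint64 array
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return float((s0 + s1) >> np.uint64(11)) * _INV53


@njit(cache=True)
def _rng_init(seed):
    # SplitMix64 expansion of the integer seed into the xorshift state
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z += np.uint64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = x ^ (x >> np.uint64(31))
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _pow_int(x, e):
    r = 1.0
    for _ in range(e):
        r *= x
    return r


@njit(cache=True, inline="always")
def _set(prop, k, ch, val):
    d = val - prop[k, ch]
    prop[k, ch] = val
    return d


@njit(cache=True, inline="always")
def _tree_add(tree, Kpad, k, d):
    i = Kpad + k
    while i >= 1:
        tree[i] += d
        i >>= 1


@njit(cache=True)
def _voxel_props(X, k, prop, aD, aN, aM, aP, anV, mD, mN, mM, mP, mn,
                 KMV, KnV, kk, hh, outf):
    D = float(X[k, 0])
    N = float(X[k, 1])
    M = float(X[k, 2])
    P = float(X[k, 3])
    n = float(X[k, 4])
    Din = float(X[k, 5])
    prop[k, 0] = aD * n
    prop[k, 1] = aM * N / (1.0 + _pow_int(P / KMV, kk))
    prop[k, 2] = aP * M
    prop[k, 3] = anV / (1.0 + _pow_int(P / KnV, hh))
    prop[k, 4] = mD * D
    prop[k, 5] = mN * N
    prop[k, 6] = mM * M
    prop[k, 7] = mP * P
    prop[k, 8] = mn * n
    prop[k, 9] = aN * D
    prop[k, 10] = aN * outf[k] * Din


@njit(cache=True)
def _rebuild(X, prop, tree, Kpad, K, aD, aN, aM, aP, anV, mD, mN, mM, mP, mn,
             KMV, KnV, kk, hh, outf):
    for k in range(K):
        _voxel_props(X, k, prop, aD, aN, aM, aP, anV, mD, mN, mM, mP, mn,
                     KMV, KnV, kk, hh, outf)
        s = 0.0
        for c in range(11):
            s += prop[k, c]
        tree[Kpad + k] = s
    for i in range(Kpad + K, 2 * Kpad):
        tree[i] = 0.0
    for i in range(Kpad - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]


@njit(cache=True, fastmath=True)
def ssa_core(X, out_times, aD, aN, aM, aP, anV, mD, mN, mM, mP, mn,
             KMV, KnV, kk, hh, tptr, tidx, tcum, outf, seed):
    rng = _rng_init(seed)
    K = X.shape[0]
    T = out_times.shape[0]
    t_end = out_times[T - 1]
    X_out = np.zeros((T, K, 6), dtype=np.int64)
    Kpad = 1
    while Kpad < K:
        Kpad *= 2
    tree = np.zeros(2 * Kpad)
    prop = np.zeros((K, 11))
    # scan channels in rough order of decreasing traffic
    scan_order = np.array([9, 10, 5, 1, 2, 7, 3, 8, 6, 0, 4], dtype=np.int64)
    _rebuild(X, prop, tree, Kpad, K, aD, aN, aM, aP, anV, mD, mN, mM, mP, mn,
             KMV, KnV, kk, hh, outf)

    t = 0.0
    it = 0
    n_events = 0
    since_rebuild = 0
    while True:
        total = tree[1]
        if total <= 1e-300:
            break
        t += -np.log(_rng_u01(rng)) / total
        if t > t_end:
            break
        while it < T and out_times[it] < t:
            X_out[it] = X
            it += 1

        # select voxel by tree descent; the residual is uniform on the leaf
        r = _rng_u01(rng) * total
        node = 1
        while node < Kpad:
            node <<= 1
            v = tree[node]
            if r >= v:
                r -= v
                node += 1
        k = node - Kpad
        if k >= K:
            k = K - 1
        ch = -1
        for ci in range(11):
            c = scan_order[ci]
            p_c = prop[k, c]
            if r < p_c:
                ch = c
                break
            r -= p_c
        if ch < 0 or prop[k, ch] <= 0.0:
            # numerical drift: fall back to the largest channel
            ch = 0
            for c in range(11):
                if prop[k, c] > prop[k, ch]:
                    ch = c
            if prop[k, ch] <= 0.0:
                _rebuild(X, prop, tree, Kpad, K, aD, aN, aM, aP, anV,
                         mD, mN, mM, mP, mn, KMV, KnV, kk, hh, outf)
                continue

        d = 0.0
        if ch == 9:
            X[k, 5] += 1
            d += _set(prop, k, 10, aN * outf[k] * X[k, 5])
        elif ch == 10:  # transport (or boundary sink)
            X[k, 5] -= 1
            if X[k, 5] < 0:
                return X_out, np.int64(-1)
            d += _set(prop, k, 10, aN * outf[k] * X[k, 5])
            u = _rng_u01(rng)
            lo = tptr[k]
            hi = tptr[k + 1]
            l = np.int64(-1)
            for j in range(lo, hi):
                if u < tcum[j]:
                    l = tidx[j]
                    break
            if l >= 0:
                X[l, 1] += 1
                P = float(X[l, 3])
                dl = _set(prop, l, 1, aM * X[l, 1] / (1.0 + _pow_int(P / KMV, kk)))
                dl += _set(prop, l, 5, mN * X[l, 1])
                _tree_add(tree, Kpad, l, dl)
        elif ch == 5:
            X[k, 1] -= 1
            if X[k, 1] < 0:
                return X_out, np.int64(-1)
            P = float(X[k, 3])
            d += _set(prop, k, 1, aM * X[k, 1] / (1.0 + _pow_int(P / KMV, kk)))
            d += _set(prop, k, 5, mN * X[k, 1])
        elif ch == 1:
            X[k, 2] += 1
            d += _set(prop, k, 2, aP * X[k, 2])
            d += _set(prop, k, 6, mM * X[k, 2])
        elif ch == 2:
            X[k, 3] += 1
            P = float(X[k, 3])
            d += _set(prop, k, 1, aM * X[k, 1] / (1.0 + _pow_int(P / KMV, kk)))
            d += _set(prop, k, 3, anV / (1.0 + _pow_int(P / KnV, hh)))
            d += _set(prop, k, 7, mP * P)
        elif ch == 7:
            X[k, 3] -= 1
            if X[k, 3] < 0:
                return X_out, np.int64(-1)
            P = float(X[k, 3])
            d += _set(prop, k, 1, aM * X[k, 1] / (1.0 + _pow_int(P / KMV, kk)))
            d += _set(prop, k, 3, anV / (1.0 + _pow_int(P / KnV, hh)))
            d += _set(prop, k, 7, mP * P)
        elif ch == 3:
            X[k, 4] += 1
            d += _set(prop, k, 0, aD * X[k, 4])
            d += _set(prop, k, 8, mn * X[k, 4])
        elif ch == 8:
            X[k, 4] -= 1
            if X[k, 4] < 0:
                return X_out, np.int64(-1)
            d += _set(prop, k, 0, aD * X[k, 4])
            d += _set(prop, k, 8, mn * X[k, 4])
        elif ch == 6:
            X[k, 2] -= 1
            if X[k, 2] < 0:
                return X_out, np.int64(-1)
            d += _set(prop, k, 2, aP * X[k, 2])
            d += _set(prop, k, 6, mM * X[k, 2])
        elif ch == 0:
            X[k, 0] += 1
            d += _set(prop, k, 4, mD * X[k, 0])
            d += _set(prop, k, 9, aN * X[k, 0])
        else:  # ch == 4
            X[k, 0] -= 1
            if X[k, 0] < 0:
                return X_out, np.int64(-1)
            d += _set(prop, k, 4, mD * X[k, 0])
            d += _set(prop, k, 9, aN * X[k, 0])
        _tree_add(tree, Kpad, k, d)

        n_events += 1
        since_rebuild += 1
        if since_rebuild >= 8_000_000:
            since_rebuild = 0
            _rebuild(X, prop, tree, Kpad, K, aD, aN, aM, aP, anV,
                     mD, mN, mM, mP, mn, KMV, KnV, kk, hh, outf)

    while it < T:
        X_out[it] = X
        it += 1
    return X_out, np.int64(n_events)
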