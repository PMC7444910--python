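"""Direct-method Gillespie kernel for multi-type branching clones.

The kernel is written once in array code and compiled with numba when it is
importable; otherwise the identical pure-Python path runs (slowly). Random
numbers come from an inlined xorshift128+ generator so that both paths are
bit-identical and every clone is reproducible from its two 64-bit seed words.

Status codes: 0 = completed, 1 = runaway population (max_cells exceeded).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def _rand(state):
    """xorshift128+ on a 2-word uint64 state; returns a double in (0, 1]."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    s1 = s1 ^ s0 ^ (s1 >> _U64(17)) ^ (s0 >> _U64(26))
    state[1] = s1
    r = (s1 + s0) >> _U64(11)
    return (np.float64(r) + 1.0) * _INV53


@njit(cache=True)
def _run_clone(
    lam, gamma, omega, a_state,
    pair_off, pair_cnt, pair_j, pair_k, pair_cum,
    n, check_times, out, max_cells, rng_state,
):
    """Simulate one clone in place.

    ``n`` is the per-state count vector (modified), ``out`` has shape
    ``(len(check_times), m)``. Returns (extinction_time, status); extinction
    time is +inf for clones still alive at the final checkpoint.
    """
    m = lam.shape[0]
    T = check_times.shape[0]
    t = 0.0
    ci = 0
    ntot = 0
    for i in range(m):
        ntot += n[i]
    ext_time = np.inf
    status = 0
    t_end = check_times[T - 1]
    while True:
        # total propensity recomputed exactly every event: incremental
        # updates drift and bias both waiting times and state selection
        R_tot = 0.0
        for i in range(m):
            R_tot += n[i] * a_state[i]
        if R_tot <= 0.0 or ntot == 0:
            # frozen (no active process) or extinct: counts stay put
            while ci < T:
                for i in range(m):
                    out[ci, i] = n[i]
                ci += 1
            break
        dt = -np.log(_rand(rng_state)) / R_tot
        t_new = t + dt
        while ci < T and check_times[ci] < t_new:
            for i in range(m):
                out[ci, i] = n[i]
            ci += 1
        if ci >= T or t_new > t_end:
            while ci < T:
                for i in range(m):
                    out[ci, i] = n[i]
                ci += 1
            break
        # pick the state of the reacting cell, proportional to n_i * a_i
        u = _rand(rng_state) * R_tot
        i = -1
        acc = 0.0
        for s in range(m):
            if n[s] > 0 and a_state[s] > 0.0:
                i = s
                acc += n[s] * a_state[s]
                if u <= acc:
                    break
        # pick the event within the state: loss | division | transition,
        # with boundary draws resolved towards a positive-rate channel
        v = _rand(rng_state) * a_state[i]
        is_loss = gamma[i] > 0.0 and v >= a_state[i] - gamma[i]
        is_division = False
        j = -1
        if not is_loss:
            v -= lam[i]
            if v < 0.0:
                is_division = True
            else:
                for s in range(m):
                    if s == i:
                        continue
                    if omega[i, s] > 0.0:
                        j = s
                        v -= omega[i, s]
                        if v < 0.0:
                            break
                if j < 0:
                    is_division = True  # roundoff at the division boundary
        if is_loss:
            n[i] -= 1
            ntot -= 1
        elif is_division:
            # division: draw an unordered daughter pair
            w = _rand(rng_state)
            base = pair_off[i]
            idx = base
            for q in range(pair_cnt[i]):
                idx = base + q
                if w <= pair_cum[idx]:
                    break
            n[i] -= 1
            n[pair_j[idx]] += 1
            n[pair_k[idx]] += 1
            ntot += 1
        else:
            # transition i -> j
            n[i] -= 1
            n[j] += 1
        t = t_new
        if ntot == 0:
            ext_time = t
        if ntot > max_cells:
            status = 1
            while ci < T:
                for i in range(m):
                    out[ci, i] = n[i]
                ci += 1
            break
    return ext_time, status


@njit(cache=True)
def _run_ensemble(
    lam, gamma, omega, a_state,
    pair_off, pair_cnt, pair_j, pair_k, pair_cum,
    init_idx, check_times, n_clones, seeds, max_cells,
):
    m = lam.shape[0]
    T = check_times.shape[0]
    counts = np.zeros((n_clones, T, m), dtype=np.int64)
    ext = np.empty(n_clones, dtype=np.float64)
    status = np.zeros(n_clones, dtype=np.int8)
    n = np.zeros(m, dtype=np.int64)
    rng_state = np.empty(2, dtype=np.uint64)
    for c in range(n_clones):
        for i in range(m):
            n[i] = 0
        n[init_idx] = 1
        rng_state[0] = seeds[c, 0]
        rng_state[1] = seeds[c, 1]
        e, st = _run_clone(
            lam, gamma, omega, a_state,
            pair_off, pair_cnt, pair_j, pair_k, pair_cum,
            n, check_times, counts[c], max_cells, rng_state,
        )
        ext[c] = e
        status[c] = st
    return counts, ext, status
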