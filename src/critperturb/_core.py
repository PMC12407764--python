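"""Numba kernel for the excitable-lattice simulation.

The lattice dynamics are a 3-state probabilistic cellular automaton
(rest -> active -> refractory -> rest).  A resting unit becomes active when it
is hit by at least one of three independent Bernoulli sources within a step:
external Poisson drive (p_poiss), optional stimulation drive on a single
target unit (p_stim), or per-edge transmission from each active presynaptic
neighbour (p_trans per edge).  Per-edge and per-unit Bernoulli processes are
realised exactly, using geometric-gap skipping so the cost per step scales
with the number of active units, not with lattice size.

Update order within a tick t: units activated at tick t-1 transmit; resting
units sample their activation (recorded as spikes of tick t); finally the
transmitters enter refractoriness for `refr_steps` ticks.  A unit is thereby
shielded from re-activation for refr_steps + 1 activation phases after its
spike, so an isolated unit under drive q has stationary active fraction
q/(1+2q) with the default 1-step refractory period (minimum inter-spike
interval of 3 ticks).

All randomness comes from numba's per-thread NumPy legacy RNG, seeded once
per call: identical arguments give bit-identical output.
"""

from __future__ import annotations

import numpy as np
import numba as nb

REST = 0
ACTIVE = 1
REFRACTORY = 2


@nb.njit(cache=True)
def _grow_i64(arr, cnt):
    out = np.empty(max(2 * arr.shape[0], 1024), dtype=np.int64)
    out[:cnt] = arr[:cnt]
    return out


@nb.njit(cache=True)
def bernoulli_indices(n, p):
    """Indices of successes of n iid Bernoulli(p) trials via geometric gaps."""
    out = np.empty(16, dtype=np.int64)
    cnt = 0
    if p <= 0.0:
        return out[:0]
    if p >= 1.0:
        return np.arange(n)
    log1mp = np.log1p(-p)
    i = -1
    while True:
        i += 1 + int(np.floor(np.log(np.random.random()) / log1mp))
        if i >= n:
            break
        if cnt == out.shape[0]:
            tmp = np.empty(2 * cnt, dtype=np.int64)
            tmp[:cnt] = out
            out = tmp
        out[cnt] = i
        cnt += 1
    return out[:cnt]


@nb.njit(cache=True)
def sample_edges(p_flat, n, seed):
    """For each offset class o, draw iid Bernoulli(p_flat[o]) over n sources.

    Returns parallel (source, offset) arrays; exact realisation of the
    independent per-ordered-pair connection draws.
    """
    np.random.seed(seed)
    cap = max(int(n * p_flat.sum() * 1.2) + 1024, 1024)
    src = np.empty(cap, dtype=np.int64)
    off = np.empty(cap, dtype=np.int64)
    cnt = 0
    for o in range(p_flat.shape[0]):
        p = p_flat[o]
        if p <= 0.0:
            continue
        if p >= 1.0:
            for i in range(n):
                if cnt == src.shape[0]:
                    src = _grow_i64(src, cnt)
                    off = _grow_i64(off, cnt)
                src[cnt] = i
                off[cnt] = o
                cnt += 1
            continue
        log1mp = np.log1p(-p)
        i = -1
        while True:
            i += 1 + int(np.floor(np.log(np.random.random()) / log1mp))
            if i >= n:
                break
            if cnt == src.shape[0]:
                src = _grow_i64(src, cnt)
                off = _grow_i64(off, cnt)
            src[cnt] = i
            off[cnt] = o
            cnt += 1
    return src[:cnt], off[:cnt]


@nb.njit(cache=True)
def simulate(indptr, indices, n_units, p_trans, p_poiss, refr_steps,
             n_steps, state0, stim_units, stim_onsets, stim_len, p_stim,
             fov_local, record_from, seed):
    """Run the automaton for n_steps.

    Parameters
    ----------
    indptr, indices : CSR arrays of the directed adjacency (row = presynaptic).
    state0 : int8 per-unit initial state (REST/ACTIVE/REFRACTORY).
    stim_units, stim_onsets : parallel arrays of non-overlapping stimulation
        trials; during steps [onset, onset + stim_len) the unit receives
        extra drive p_stim while resting.
    fov_local : int32 per-unit map to a recording channel, -1 = not recorded.
    record_from : first step index at which spike events are stored.

    Returns
    -------
    ev_step, ev_unit : recorded spike events (step, channel).
    active_counts : number of units activated at every step (whole lattice).
    state : final per-unit state.
    """
    np.random.seed(seed)
    state = state0.copy()

    active = np.empty(n_units, dtype=np.int64)
    n_active = 0
    refr_u = np.empty(n_units, dtype=np.int64)
    refr_t = np.empty(n_units, dtype=np.int32)
    refr_u2 = np.empty(n_units, dtype=np.int64)
    refr_t2 = np.empty(n_units, dtype=np.int32)
    n_refr = 0
    for i in range(n_units):
        if state[i] == ACTIVE:
            active[n_active] = i
            n_active += 1
        elif state[i] == REFRACTORY:
            refr_u[n_refr] = i
            refr_t[n_refr] = refr_steps
            n_refr += 1

    hit = np.zeros(n_units, dtype=nb.boolean)
    touched = np.empty(n_units, dtype=np.int64)
    new_active = np.empty(n_units, dtype=np.int64)

    ev_step = np.empty(1024, dtype=np.int64)
    ev_unit = np.empty(1024, dtype=np.int32)
    ev_cnt = 0

    active_counts = np.empty(n_steps, dtype=np.int64)
    n_trials = stim_units.shape[0]
    trial_ptr = 0

    use_skip = 0.0 < p_trans < 0.25
    log1mpt = np.log1p(-p_trans) if use_skip else 0.0

    for t in range(n_steps):
        # transmission attempts from units activated last tick
        n_touched = 0
        for a in range(n_active):
            u = active[a]
            lo = indptr[u]
            hi = indptr[u + 1]
            if use_skip:
                e = lo - 1
                while True:
                    e += 1 + int(np.floor(np.log(np.random.random()) / log1mpt))
                    if e >= hi:
                        break
                    j = indices[e]
                    if not hit[j]:
                        hit[j] = True
                        touched[n_touched] = j
                        n_touched += 1
            elif p_trans > 0.0:
                for e in range(lo, hi):
                    if np.random.random() < p_trans:
                        j = indices[e]
                        if not hit[j]:
                            hit[j] = True
                            touched[n_touched] = j
                            n_touched += 1

        # which stimulation trial (if any) covers this step
        while trial_ptr < n_trials and t >= stim_onsets[trial_ptr] + stim_len:
            trial_ptr += 1
        stim_u = -1
        if trial_ptr < n_trials and stim_onsets[trial_ptr] <= t:
            stim_u = int(stim_units[trial_ptr])

        # activation of resting units: transmission hits, Poisson drive, stim
        n_new = 0
        for a in range(n_touched):
            j = touched[a]
            if state[j] == REST:
                state[j] = ACTIVE
                new_active[n_new] = j
                n_new += 1
        if p_poiss > 0.0:
            if p_poiss >= 1.0:
                for j in range(n_units):
                    if state[j] == REST:
                        state[j] = ACTIVE
                        new_active[n_new] = j
                        n_new += 1
            else:
                log1mq = np.log1p(-p_poiss)
                i = -1
                while True:
                    i += 1 + int(np.floor(np.log(np.random.random()) / log1mq))
                    if i >= n_units:
                        break
                    if state[i] == REST:
                        state[i] = ACTIVE
                        new_active[n_new] = i
                        n_new += 1
        if stim_u >= 0 and state[stim_u] == REST:
            if np.random.random() < p_stim:
                state[stim_u] = ACTIVE
                new_active[n_new] = stim_u
                n_new += 1

        # refractory countdown, then last tick's transmitters enter
        # refractoriness; both happen after the activation draw so a unit is
        # shielded for refr_steps + 1 activation phases following its spike
        m = 0
        for a in range(n_refr):
            rt = refr_t[a] - 1
            if rt == 0:
                state[refr_u[a]] = REST
            else:
                refr_u2[m] = refr_u[a]
                refr_t2[m] = rt
                m += 1
        for a in range(n_active):
            u = active[a]
            if refr_steps > 0:
                state[u] = REFRACTORY
                refr_u2[m] = u
                refr_t2[m] = refr_steps
                m += 1
            else:
                state[u] = REST
        refr_u, refr_u2 = refr_u2, refr_u
        refr_t, refr_t2 = refr_t2, refr_t
        n_refr = m

        for a in range(n_touched):
            hit[touched[a]] = False
        for a in range(n_new):
            active[a] = new_active[a]
        n_active = n_new
        active_counts[t] = n_active

        if t >= record_from:
            for a in range(n_active):
                ch = fov_local[active[a]]
                if ch >= 0:
                    if ev_cnt == ev_step.shape[0]:
                        ev_step = _grow_i64(ev_step, ev_cnt)
                        tmp = np.empty(ev_step.shape[0], dtype=np.int32)
                        tmp[:ev_cnt] = ev_unit[:ev_cnt]
                        ev_unit = tmp
                    ev_step[ev_cnt] = t
                    ev_unit[ev_cnt] = ch
                    ev_cnt += 1

    return ev_step[:ev_cnt], ev_unit[:ev_cnt], active_counts, state
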