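"""JIT-compiled inner loop of the branching simulation.

The production simulator does not draw one Bernoulli variate per connection.
Each neuron's target list is sorted ascending by distance, so the activation
probabilities p = m*w along a row are non-increasing.  This permits an exact
geometric-skip (thinning) scheme: from position ``pos`` draw the offset of
the first success of a Bernoulli(q) sequence with envelope ``q = m*w[pos]``
(a geometric variate), land on a candidate, and accept it with probability
``p_candidate / q``.  Marginal success probabilities are exactly ``m*w_j``
per target and targets are visited in list order, so the semantics —
including the coalescence fallback, which walks the same ordered list — are
identical to the naive per-target update, at O(active * m) expected draws
per step instead of O(active * K).
"""

import numpy as np
from numba import njit

__all__ = ["run_branching"]


@njit(cache=False)
def run_branching(
    indptr,
    targets,
    weights,
    m,
    h,
    n_steps,
    n_neurons,
    seed,
    max_spikes,
    compensate,
):
    """Simulate the driven branching process; returns sparse spike lists.

    Returns (spike_steps, spike_neurons, n_recorded_steps, n_saturated,
    overflowed).  If the spike buffer fills, the run stops early and
    ``n_recorded_steps`` < ``n_steps``.
    """
    np.random.seed(seed)
    next_flag = np.zeros(n_neurons, dtype=np.uint8)
    cur = np.empty(n_neurons, dtype=np.int64)
    nxt = np.empty(n_neurons, dtype=np.int64)
    perm = np.arange(n_neurons)
    n_cur = 0
    spike_t = np.empty(max_spikes, dtype=np.int32)
    spike_i = np.empty(max_spikes, dtype=np.int32)
    n_sp = 0
    n_saturated = 0
    overflowed = False
    steps_done = 0

    for t in range(n_steps):
        if n_sp + n_cur > max_spikes:
            overflowed = True
            break
        for a in range(n_cur):
            spike_t[n_sp] = t
            spike_i[n_sp] = cur[a]
            n_sp += 1
        steps_done = t + 1

        n_nxt = 0
        if m > 0.0:
            for a in range(n_cur):
                i = cur[a]
                lo = indptr[i]
                hi = indptr[i + 1]
                pos = lo
                while pos < hi:
                    q = m * weights[pos]
                    if q <= 0.0:
                        break
                    u = np.random.random()
                    if u < 1e-300:
                        u = 1e-300
                    g = int(np.floor(np.log(u) / np.log(1.0 - q)))
                    pos = pos + g
                    if pos >= hi:
                        break
                    p = m * weights[pos]
                    if np.random.random() * q < p:
                        j = targets[pos]
                        if next_flag[j] == 0:
                            next_flag[j] = 1
                            nxt[n_nxt] = j
                            n_nxt += 1
                        elif compensate:
                            # redirect to the next quiescent target in this
                            # neuron's distance-sorted list, wrapping once
                            found = np.int64(-1)
                            for k in range(pos + 1, hi):
                                if next_flag[targets[k]] == 0:
                                    found = k
                                    break
                            if found < 0:
                                for k in range(lo, pos):
                                    if next_flag[targets[k]] == 0:
                                        found = k
                                        break
                            if found >= 0:
                                j2 = targets[found]
                                next_flag[j2] = 1
                                nxt[n_nxt] = j2
                                n_nxt += 1
                    pos += 1

        if h > 0.0:
            # uniform random subset of size Binomial(N, h): partial
            # Fisher-Yates over a persistent permutation buffer
            n_spont = np.random.binomial(n_neurons, h)
            for idx in range(n_spont):
                r = idx + np.random.randint(0, n_neurons - idx)
                tmp = perm[idx]
                perm[idx] = perm[r]
                perm[r] = tmp
                j = perm[idx]
                if next_flag[j] == 0:
                    next_flag[j] = 1
                    nxt[n_nxt] = j
                    n_nxt += 1

        if n_nxt == n_neurons:
            n_saturated += 1
        for a in range(n_nxt):
            next_flag[nxt[a]] = 0
            cur[a] = nxt[a]
        n_cur = n_nxt

    return spike_t[:n_sp].copy(), spike_i[:n_sp].copy(), steps_done, n_saturated, overflowed
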