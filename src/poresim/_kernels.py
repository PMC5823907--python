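"""Numba-compiled inner loops for cell motility.

The run-and-tumble substep loop touches every cell many times per engine
step, so it is compiled with numba and draws from an inline xorshift64*
generator (cheaper than the global Mersenne state, deterministic from the
per-call seed, and statistically ample for Bernoulli tumbling draws and
uniform junction choices).
"""

import numpy as np
from numba import njit

_INV_2_64 = 1.0 / 2.0**64


@njit(inline="always", cache=False)
def _next_uniform(state):
    # xorshift64* (Vigna); state must be non-zero
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    return x, np.float64(x * np.uint64(2685821657736338717)) * _INV_2_64


@njit(cache=False)
def advance_kernel(
    channel,      # int64[n]  in/out
    offset,       # float64[n] in/out
    heading,      # int8[n]   in/out
    species,      # int8[n]
    tumble_p,     # float64[2, n_channels, 2] substep tumble probability,
                  # indexed [species, channel, 0 if heading +1 else 1]
    ch_a,         # int64[n_channels]
    ch_b,         # int64[n_channels]
    ch_len,       # float64[n_channels]
    indptr,       # int64[n_nodes+1] node -> incident channel CSR
    indices,      # int64[:]
    v_dt,         # float64 distance per substep
    n_sub,        # int
    seed,         # int
):
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    if state == np.uint64(0):
        state = np.uint64(0x9E3779B97F4A7C15)
    n = channel.size
    for _ in range(n_sub):
        for i in range(n):
            c = channel[i]
            h = heading[i]
            d = 0 if h > 0 else 1
            # an in-channel tumble reverts the heading with probability 1/2,
            # otherwise the run continues unchanged; only the reversal arm
            # affects the position, so one draw against p/2 suffices
            state, u = _next_uniform(state)
            if u < 0.5 * tumble_p[species[i], c, d]:
                h = -h
            x = offset[i] + h * v_dt
            # crossing a junction forces a tumble: uniform choice among all
            # incident channels (arrival channel included); run continues
            guard = 0
            while (x < 0.0 or x > ch_len[c]) and guard < 64:
                if x < 0.0:
                    node = ch_a[c]
                    leftover = -x
                else:
                    node = ch_b[c]
                    leftover = x - ch_len[c]
                k0 = indptr[node]
                deg = indptr[node + 1] - k0
                state, u = _next_uniform(state)
                c = indices[k0 + np.int64(u * deg)]
                if ch_a[c] == node:
                    h = 1
                    x = leftover
                else:
                    h = -1
                    x = ch_len[c] - leftover
                guard += 1
            if x < 0.0:
                x = 0.0
            elif x > ch_len[c]:
                x = ch_len[c]
            channel[i] = c
            offset[i] = x
            heading[i] = h
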