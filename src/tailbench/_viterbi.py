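"""Duration-expanded Viterbi decoding for the 4-state linear-chain model.

Each of the four read regions (adapter, RTA, poly(A), transcript) is one
HMM state with a Gaussian emission. Minimum state durations are enforced by
expanding every state into ``min_dur`` copies: transitions between copies
of the same state are deterministic (log-probability 0), the last copy of a
state self-loops with log p_self and advances to the next state's first
copy with log(1 - p_self). The path must start in the first copy of state 0
and end in the last copy of state 3, so every state is visited for at least
its minimum duration.

Under this model the log-probability of a segmentation with per-state
durations d_s over a read of length T is

    sum_t log N(x_t; mu_{q_t}, sigma_{q_t})
      + sum_s (d_s - min_dur_s) * log p_self_s
      + sum_{s<3} log(1 - p_self_s),

which is exactly what the exhaustive oracle in ``segmentation`` computes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _viterbi_kernel(x, mu, sd, log_self, log_adv, min_dur):  # pragma: no cover
    T = x.shape[0]
    S = mu.shape[0]
    D = 0
    for s in range(S):
        D += min_dur[s]
    # copy -> state, and flags for first/last copy of each state
    state_of = np.empty(D, np.int64)
    is_first = np.zeros(D, np.bool_)
    is_last = np.zeros(D, np.bool_)
    j = 0
    for s in range(S):
        for k in range(min_dur[s]):
            state_of[j] = s
            if k == 0:
                is_first[j] = True
            if k == min_dur[s] - 1:
                is_last[j] = True
            j += 1

    neg_inf = -np.inf
    v_prev = np.full(D, neg_inf)
    v_cur = np.full(D, neg_inf)
    choice = np.zeros((T, D), np.int8)  # 0 = stay (self-loop), 1 = advance

    # emission log-likelihood per state at one sample
    def emis(s, xt):
        z = (xt - mu[s]) / sd[s]
        return -0.5 * z * z - np.log(sd[s]) - 0.5 * _LOG2PI

    v_prev[0] = emis(0, x[0])
    for t in range(1, T):
        xt = x[t]
        for jj in range(D):
            s = state_of[jj]
            best = neg_inf
            ch = np.int8(1)
            if is_last[jj]:
                stay = v_prev[jj] + log_self[s]
                if stay > neg_inf:
                    best = stay
                    ch = np.int8(0)
            if is_first[jj]:
                if jj > 0:  # from previous state's last copy
                    adv = v_prev[jj - 1] + log_adv[s - 1]
                    if adv > best:
                        best = adv
                        ch = np.int8(1)
            else:  # forced advance from previous copy of the same state
                adv = v_prev[jj - 1]
                if adv > best:
                    best = adv
                    ch = np.int8(1)
            if best > neg_inf:
                best += emis(s, xt)
            v_cur[jj] = best
            choice[t, jj] = ch
        v_prev, v_cur = v_cur, v_prev

    logp = v_prev[D - 1]
    # backtrack from the last copy of the last state
    path = np.empty(T, np.int64)
    jj = D - 1
    for t in range(T - 1, -1, -1):
        path[t] = state_of[jj]
        if t > 0 and choice[t, jj] == 1:
            jj -= 1
    return logp, path
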