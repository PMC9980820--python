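"""Numba-compiled simulation kernel.

Bit-identical to the pure-Python reference in :mod:`boldsim.engine`: both
consume the supplied ``numpy.random.Generator`` in exactly the same order
(n speed draws; per period a Fisher-Yates shuffle of the not-yet-arrived
agents, then per scheduled agent one uniform draw plus, on a
nearest-neighbour tie, one bounded integer draw).  Rule codes follow
``engine.RULES`` order: 0 central, 1 nearest_neighbour, 2 majority,
3 non_social.  A returned end time of -1 signals that ``max_steps`` was
exceeded.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_kernel(g, n, p_baseline, omega_difference, omega_offset, d_food,
                    threshold, rule, max_steps):
    s = np.empty(n)
    p = np.empty(n)
    omega = np.empty(n)
    d = np.zeros(n)
    for i in range(n):
        s[i] = 0.95 + 0.05 * g.random()
    for i in range(n):
        omega[i] = (i + omega_offset) * omega_difference
        p[i] = p_baseline
    leave = np.full(n, -1, np.int64)
    arrive = np.full(n, -1, np.int64)
    # only not-yet-arrived agents are scheduled; arrived ones are frozen and
    # their p is never read again, so this is behaviourally identical to
    # shuffling the whole group while consuming far fewer draws
    active = np.arange(n)
    n_active = n
    t = 0
    while n_active > 0:
        t += 1
        if t > max_steps:
            return leave, arrive, np.int64(-1), s
        for k in range(n_active - 1, 0, -1):
            j = g.integers(0, k + 1)
            tmp = active[k]
            active[k] = active[j]
            active[j] = tmp
        for idx in range(n_active):
            i = active[idx]
            p[i] += omega[i]
            di = d[i]
            if di >= d_food:
                continue
            if di < 0.0:
                d[i] = di + s[i]
            else:
                u = g.random()
                if u < p[i]:
                    d[i] = di + s[i]
                elif rule == 0:  # central: toward the mean of the others
                    total = 0.0
                    for jj in range(n):
                        total += d[jj]
                    d_prime = (total - di) / (n - 1)
                    if d_prime > di:
                        d[i] = di + s[i]
                    elif d_prime < di:
                        d[i] = di - s[i]
                elif rule == 1:  # nearest neighbour, random among ties
                    d_min = np.inf
                    m = 0
                    for jj in range(n):
                        if jj == i:
                            continue
                        dist = abs(d[jj] - di)
                        if dist < d_min:
                            d_min = dist
                            m = 1
                        elif dist == d_min:
                            m += 1
                    if m > 1:
                        pick = g.integers(0, m)
                    else:
                        pick = 0
                    c = 0
                    target = di
                    for jj in range(n):
                        if jj == i:
                            continue
                        if abs(d[jj] - di) == d_min:
                            if c == pick:
                                target = d[jj]
                                break
                            c += 1
                    if target > di:
                        d[i] = di + s[i]
                    elif target < di:
                        d[i] = di - s[i]
                elif rule == 2:  # majority by strict position comparison
                    ahead = 0
                    behind = 0
                    for jj in range(n):
                        if jj == i:
                            continue
                        if d[jj] > di:
                            ahead += 1
                        elif d[jj] < di:
                            behind += 1
                    if ahead > behind:
                        d[i] = di + s[i]
                    elif behind > ahead:
                        d[i] = di - s[i]
                # rule 3 (non_social): failed draw means no move
            if leave[i] < 0 and d[i] >= threshold:
                leave[i] = t
            if arrive[i] < 0 and d[i] >= d_food:
                arrive[i] = t
        # compact at period end, preserving the shuffled order
        w = 0
        for idx in range(n_active):
            i = active[idx]
            if arrive[i] < 0:
                active[w] = i
                w += 1
        n_active = w
    return leave, arrive, np.int64(t), s
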